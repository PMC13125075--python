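"""Readers and writers for on-disk artifacts.

Everything the pipeline touches on disk is delimited text: square
connectivity matrices and time-series matrices (comma- or tab-separated,
'.' decimal, optional single header row, dialect auto-detected per file),
BIDS-derivatives style confounds TSVs, subject tables and gradient tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DialectError, FormatError

MATRIX_FLOAT_FORMAT = "%.10g"  # declared round-trip precision


# ---------------------------------------------------------------------------
# matrices

def read_matrix(path: str | Path) -> np.ndarray:
    """Read a rectangular numeric matrix from delimited text.

    Detects comma vs tab/whitespace separation and an optional single header
    row (and a leading label column written by :func:`write_matrix` with
    ``labels=``). Ragged rows or non-numeric cells raise
    :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    sep = "," if lines[0].count(",") >= lines[0].count("\t") and "," in lines[0] else None
    rows = [ln.split(",") if sep else ln.split() for ln in lines]
    widths = {len(r) for r in rows}

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    start_row = 0 if all(_numeric(c) for c in rows[0]) else 1
    body = rows[start_row:]
    if not body:
        raise FormatError(f"{path}: header but no data rows")
    if len({len(r) for r in body}) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    start_col = 0 if _numeric(body[0][0]) else 1
    out = np.empty((len(body), len(body[0]) - start_col), dtype=float)
    for i, r in enumerate(body):
        for j, cell in enumerate(r[start_col:]):
            if not _numeric(cell):
                raise FormatError(f"{path}: non-numeric cell {cell!r} at row {i}")
            out[i, j] = float(cell)
    return out


def write_matrix(values: np.ndarray, path: str | Path,
                 labels: list[str] | None = None, sep: str = "\t") -> None:
    """Write a matrix as delimited text (optionally with a label header)."""
    values = np.asarray(values, dtype=float)
    path = Path(path)
    with path.open("w") as fh:
        if labels is not None:
            if len(labels) != values.shape[1]:
                raise FormatError("label count does not match column count")
            fh.write(sep.join(labels) + "\n")
        for row in values:
            fh.write(sep.join(MATRIX_FLOAT_FORMAT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# confounds

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: Confounds dialects: required named columns + required column prefixes.
CONFOUND_DIALECTS = {
    "fmriprep": {
        "required": MOTION_COLUMNS + ("framewise_displacement", "std_dvars",
                                      "white_matter", "csf"),
        "cosine_prefix": "cosine",
    },
}


@dataclass
class ConfoundsTable:
    """Per-volume confound regressors (BIDS-derivatives layout).

    Missing values (the first volume's FD/DVARS have no predecessor) are kept
    as NaN, never silently zeroed; consumers decide how to treat them.
    """

    table: pd.DataFrame
    dialect: str = "fmriprep"

    @property
    def n_volumes(self) -> int:
        return len(self.table)

    @property
    def fd(self) -> np.ndarray:
        return self.table["framewise_displacement"].to_numpy(dtype=float)

    @property
    def std_dvars(self) -> np.ndarray:
        return self.table["std_dvars"].to_numpy(dtype=float)

    def cosine_columns(self) -> list[str]:
        prefix = CONFOUND_DIALECTS[self.dialect]["cosine_prefix"]
        return [c for c in self.table.columns if c.startswith(prefix)]


def read_confounds(path: str | Path, dialect: str = "fmriprep") -> ConfoundsTable:
    """Read a confounds TSV, validating columns against the dialect."""
    if dialect not in CONFOUND_DIALECTS:
        raise DialectError(f"unknown confounds dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", na_values=["n/a", "N/A", "NA"])
    missing = [c for c in CONFOUND_DIALECTS[dialect]["required"] if c not in df.columns]
    if missing:
        raise DialectError(f"{path}: missing required columns {missing} "
                           f"for dialect {dialect!r}")
    fd = df["framewise_displacement"]
    if (fd.dropna() < 0).any():
        raise FormatError(f"{path}: negative framewise displacement")
    return ConfoundsTable(df, dialect=dialect)


# ---------------------------------------------------------------------------
# subject (cohort) tables

COHORT_COLUMNS = ("subject_id", "group", "age", "gender", "hamd")
GROUPS = ("MDD", "HC")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read the subject table (subject_id, group, age, gender, hamd)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cohort columns {missing}")
    if df["subject_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate subject ids")
    bad = set(df["group"]) - set(GROUPS)
    if bad or df["group"].isna().any():
        raise FormatError(f"{path}: invalid group labels {sorted(bad)}")
    if (df["hamd"] < 0).any():
        raise FormatError(f"{path}: negative HAM-D score")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gradient tables

def write_gradient_table(scores: np.ndarray, parcel_table: pd.DataFrame,
                         path: str | Path) -> None:
    """Write per-parcel gradient scores with parcel metadata columns."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    out = parcel_table[["parcel_id", "label", "network"]].reset_index(drop=True)
    for k in range(scores.shape[1]):
        out[f"score_g{k + 1}"] = scores[:, k]
    out.to_csv(path, index=False)


def read_gradient_table(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a gradient table; returns (scores N×k, metadata frame)."""
    df = pd.read_csv(path)
    score_cols = [c for c in df.columns if c.startswith("score_g")]
    if not score_cols:
        raise FormatError(f"{path}: no score_g* columns")
    return df[score_cols].to_numpy(dtype=float), df.drop(columns=score_cols)
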