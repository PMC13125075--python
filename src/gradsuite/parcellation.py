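"""Parcellation data model and label-table reader.

The pipeline is parcel-based throughout: a parcellation assigns every
cortical parcel to one of the seven canonical resting-state networks
(visual VN, somatomotor SMN, dorsal attention DAN, salience/ventral
attention SN, limbic LN, control CN, default mode DMN) and one hemisphere.
Insula parcels are identified purely by a label substring (Schaefer-style
labels of the form ``7Networks_LH_SalVentAttn_FrOperIns_3``), and may carry
an anatomical subdivision tag used by the insula sub-gradient analyses:
ventral anterior (vAI), dorsal anterior (dAI, including frontal-operculum
parcels) or posterior insula.

Parcel ids are 1-based on disk (Schaefer convention) and 0-based as numpy
indices; every function documents which convention it returns.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

NETWORKS = ("VN", "SMN", "DAN", "SN", "LN", "CN", "DMN")

#: Schaefer 7-network label tokens -> canonical network abbreviations.
SCHAEFER_NETWORK_TOKENS = {
    "Vis": "VN",
    "SomMot": "SMN",
    "DorsAttn": "DAN",
    "SalVentAttn": "SN",
    "Limbic": "LN",
    "Cont": "CN",
    "Default": "DMN",
}

DEFAULT_INSULA_PATTERN = "SalVentAttn_FrOperIns"

SUBDIVISIONS = ("vAI", "dAI", "dAI-frontal-operculum", "posterior", "unassigned")

#: Default insula-subdivision lookup (label suffix -> subdivision) for the six
#: parcels with published anatomical assignments; the remaining insula parcels
#: default to "unassigned" and are supplied by the user (or by the synthetic
#: parcellation, which knows its own ground truth).
DEFAULT_SUBDIVISIONS = {
    "LH_SalVentAttn_FrOperIns_1": "vAI",
    "LH_SalVentAttn_FrOperIns_3": "dAI",
    "LH_SalVentAttn_FrOperIns_8": "dAI-frontal-operculum",
    "RH_SalVentAttn_FrOperIns_2": "dAI",
    "RH_SalVentAttn_FrOperIns_6": "dAI-frontal-operculum",
    "RH_SalVentAttn_FrOperIns_7": "dAI-frontal-operculum",
}

ANTERIOR_SUBDIVISIONS = frozenset({"vAI", "dAI", "dAI-frontal-operculum"})


def parse_schaefer_label(label: str) -> tuple[str, str]:
    """Parse hemisphere and network from a Schaefer-style label.

    Returns ``(hemisphere, network)`` with hemisphere in {LH, RH} and network
    one of :data:`NETWORKS`. Raises :class:`FormatError` for labels whose
    hemisphere or network token cannot be recognised.
    """
    parts = label.split("_")
    hemi = next((p for p in parts if p in ("LH", "RH")), None)
    if hemi is None:
        raise FormatError(f"no hemisphere token (LH/RH) in label {label!r}")
    net = next((SCHAEFER_NETWORK_TOKENS[p] for p in parts if p in SCHAEFER_NETWORK_TOKENS), None)
    if net is None:
        raise FormatError(f"unparsable network token in label {label!r}")
    return hemi, net


@dataclass
class ParcellationScheme:
    """A complete parcel table.

    Attributes
    ----------
    table : DataFrame indexed 0..P-1 with columns
        ``parcel_id`` (1-based), ``label``, ``network``, ``hemisphere``,
        ``insula_subdivision`` and optionally ``mni_x/mni_y/mni_z``.
    insula_pattern : the substring that flags insula parcels.
    """

    table: pd.DataFrame
    insula_pattern: str = DEFAULT_INSULA_PATTERN

    def __post_init__(self) -> None:
        t = self.table
        ids = t["parcel_id"].to_numpy()
        if len(ids) == 0:
            raise FormatError("empty parcellation")
        if len(np.unique(ids)) != len(ids):
            raise FormatError("duplicate parcel ids")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise FormatError("parcel ids must be consecutive 1..P")
        bad = set(t["network"]) - set(NETWORKS)
        if bad:
            raise FormatError(f"unknown network tokens: {sorted(bad)}")
        if "insula_subdivision" not in t.columns:
            t["insula_subdivision"] = "unassigned"

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def networks(self) -> pd.Series:
        return self.table["network"]

    def insula_mask(self) -> np.ndarray:
        """Boolean mask (length P) of insula parcels, by label substring."""
        return self.labels.str.contains(self.insula_pattern, regex=False).to_numpy()

    def insula_indices(self) -> np.ndarray:
        """0-based indices of insula parcels, in parcel-id order."""
        return np.flatnonzero(self.insula_mask())

    def network_indices(self, network: str) -> np.ndarray:
        """0-based indices of one network's parcels, in parcel-id order."""
        if network not in NETWORKS:
            raise FormatError(f"unknown network {network!r}")
        return np.flatnonzero((self.networks == network).to_numpy())

    def network_counts(self) -> dict[str, int]:
        return {n: int((self.networks == n).sum()) for n in NETWORKS}

    def insula_table(self) -> pd.DataFrame:
        """Insula-parcel rows (label, hemisphere, subdivision), scheme order."""
        return self.table.loc[self.insula_mask(),
                              ["parcel_id", "label", "hemisphere", "insula_subdivision"]]

    def apply_subdivisions(self, lookup: dict[str, str]) -> None:
        """Assign insula subdivisions from a label(-suffix) -> tag mapping.

        Keys match if they equal the label or a trailing substring of it, so
        both full ``7Networks_...`` labels and the shorter published suffixes
        work. Unknown tags raise :class:`FormatError`.
        """
        bad = set(lookup.values()) - set(SUBDIVISIONS)
        if bad:
            raise FormatError(f"unknown subdivision tags: {sorted(bad)}")
        for key, tag in lookup.items():
            hit = self.labels.str.endswith(key)
            self.table.loc[hit, "insula_subdivision"] = tag


def read_parcellation(path: str | Path,
                      insula_pattern: str = DEFAULT_INSULA_PATTERN,
                      subdivision_lookup: dict[str, str] | None = None,
                      ) -> ParcellationScheme:
    """Read a parcellation label table from delimited text.

    Accepts the Schaefer "Centroid" CSV layout (columns: ROI id, ROI label,
    R, A, S) or any delimited table whose first two columns are a 1-based
    parcel id and a Schaefer-style label. Network and hemisphere are parsed
    from the label. The six published insula subdivision assignments are
    applied by default; ``subdivision_lookup`` entries override/extend them.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least id and label columns")
    # No-header files: first row would have a non-integer first cell.
    first_col = df.columns[0]
    try:
        int(first_col)
        df = pd.read_csv(path, sep=None, engine="python", header=None)
    except (TypeError, ValueError):
        pass
    ids = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if ids.isna().any():
        raise FormatError(f"{path}: non-integer parcel id")
    labels = df.iloc[:, 1].astype(str)
    parsed = [parse_schaefer_label(lab) for lab in labels]
    out = pd.DataFrame({
        "parcel_id": ids.astype(int).to_numpy(),
        "label": labels.to_numpy(),
        "hemisphere": [h for h, _ in parsed],
        "network": [n for _, n in parsed],
    })
    if df.shape[1] >= 5:
        xyz = df.iloc[:, 2:5].apply(pd.to_numeric, errors="coerce")
        out[["mni_x", "mni_y", "mni_z"]] = xyz.to_numpy()
    out = out.sort_values("parcel_id", ignore_index=True)
    scheme = ParcellationScheme(out, insula_pattern=insula_pattern)
    scheme.apply_subdivisions(DEFAULT_SUBDIVISIONS)
    if subdivision_lookup:
        scheme.apply_subdivisions(subdivision_lookup)
    return scheme


def write_parcellation(scheme: ParcellationScheme, path: str | Path) -> None:
    """Write the parcel table as CSV (round-trips with read_parcellation)."""
    cols = ["parcel_id", "label"]
    if "mni_x" in scheme.table.columns:
        cols += ["mni_x", "mni_y", "mni_z"]
    scheme.table[cols].to_csv(path, index=False)


def read_subdivision_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (label, subdivision) lookup table."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need label and subdivision columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
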