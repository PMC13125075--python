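"""Per-subject functional connectivity construction.

From parcel-averaged BOLD time series to Fisher-z Pearson connectivity
matrices: confound design construction (24-parameter motion model + tissue
signals + cosine high-pass basis), least-squares residualization, motion
flagging by framewise displacement / standardized DVARS, group averaging,
and alignment-based subject QC.

Conventions: connectivity matrices hold Fisher z = atanh(r) with r clipped
to |r| <= 1 - 1e-7, the diagonal fixed at 0, and are exactly symmetrized.
Motion-flagged volumes are reported but not removed unless scrubbing is
explicitly requested.
"""
from __future__ import annotations

import logging

import numpy as np

from .exceptions import ContractError, DegenerateDataError
from .io import MOTION_COLUMNS, ConfoundsTable

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7  # |r| bound before atanh

DEFAULT_FD_MM = 0.2
DEFAULT_DVARS_SD = 3.0


def flag_motion_volumes(confounds: ConfoundsTable,
                        fd_mm: float = DEFAULT_FD_MM,
                        dvars_sd: float = DEFAULT_DVARS_SD) -> np.ndarray:
    """Flag motion-contaminated volumes (FD > fd_mm OR std-DVARS > dvars_sd).

    The first volume's missing FD/DVARS are treated as 0 for flagging.
    Returns a boolean mask of length T; raises
    :class:`DegenerateDataError` if every volume is flagged.
    """
    if fd_mm <= 0 or dvars_sd <= 0:
        raise ContractError("motion thresholds must be positive")
    fd = np.nan_to_num(confounds.fd, nan=0.0)
    dvars = np.nan_to_num(confounds.std_dvars, nan=0.0)
    mask = (fd > fd_mm) | (dvars > dvars_sd)
    logger.info("flagged %d/%d volumes (FD>%g mm or std-DVARS>%g)",
                int(mask.sum()), mask.size, fd_mm, dvars_sd)
    if mask.all():
        raise DegenerateDataError("all volumes flagged as motion-contaminated")
    return mask


def build_confound_design(confounds: ConfoundsTable) -> np.ndarray:
    """Assemble the T×K confound design matrix.

    24 motion parameters (six rigid-body series, their backward-difference
    temporal derivatives with 0 in the first row, and elementwise squares of
    those 12), mean white-matter and CSF signals, and however many cosine
    high-pass regressors the table carries. K = 26 + n_cosine.
    """
    t = confounds.table
    missing = [c for c in MOTION_COLUMNS if c not in t.columns]
    if missing:
        raise ContractError(f"missing motion columns {missing}")
    motion = t.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    deriv = np.vstack([np.zeros((1, motion.shape[1])), np.diff(motion, axis=0)])
    base12 = np.hstack([motion, deriv])
    blocks = [base12, base12 ** 2,
              t[["white_matter", "csf"]].to_numpy(dtype=float)]
    cos_cols = confounds.cosine_columns()
    if cos_cols:
        blocks.append(t.loc[:, cos_cols].to_numpy(dtype=float))
    return np.hstack(blocks)


def residualize(ts: np.ndarray, regressors: np.ndarray | None = None) -> np.ndarray:
    """Residualize each parcel series on [intercept | regressors].

    Returns the least-squares residuals (same T×P shape). With no regressors
    this is column demeaning. Rank-deficient designs raise
    :class:`ContractError` naming the collinear columns.
    """
    ts = np.asarray(ts, dtype=float)
    T = ts.shape[0]
    if regressors is None or np.size(regressors) == 0:
        return ts - ts.mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(T), np.asarray(regressors, dtype=float)])
    if X.shape[1] >= T:
        raise ContractError(f"design has {X.shape[1]} columns for {T} volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        kept = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                collinear.append(j - 1)  # regressor index (0-based, sans intercept)
            else:
                kept = cand
        raise ContractError(f"rank-deficient confound design; "
                            f"collinear regressor columns {collinear}")
    beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
    return ts - X @ beta


def compute_fc(ts: np.ndarray, parcel_labels: list[str] | None = None) -> np.ndarray:
    """Pearson-correlate parcel series and Fisher-transform to a z-matrix.

    Off-diagonal entries are atanh(clip(r, ±(1−1e−7))); the diagonal is 0.
    Constant series raise :class:`DegenerateDataError` naming the parcel.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 3:
        raise ContractError("need at least 3 volumes for correlation")
    sd = ts.std(axis=0)
    tol = 1e-12 * (np.abs(ts).max(axis=0) + 1.0)
    if np.any(sd <= tol):
        bad = np.flatnonzero(sd <= tol)
        names = ([parcel_labels[i] for i in bad] if parcel_labels
                 else bad.tolist())
        raise DegenerateDataError(f"constant time series for parcels {names}")
    r = np.corrcoef(ts, rowvar=False)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def group_average(matrices: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of connectivity matrices; diagonal stays 0."""
    if not matrices:
        raise ContractError("empty matrix list")
    shapes = {m.shape for m in matrices}
    if len(shapes) != 1:
        raise ContractError(f"shape mismatch in group average: {sorted(shapes)}")
    mean = np.mean(np.stack(matrices), axis=0)
    np.fill_diagonal(mean, 0.0)
    return mean


def alignment_qc(subject_grad: np.ndarray, template_grad: np.ndarray,
                 min_r: float = 0.4) -> tuple[float, bool]:
    """QC a subject by correlating their aligned principal gradient with the
    template principal gradient. Returns (r, pass)."""
    a = np.asarray(subject_grad, dtype=float).ravel()
    b = np.asarray(template_grad, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ContractError("gradients must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("constant gradient vector in alignment QC")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, bool(r >= min_r)
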