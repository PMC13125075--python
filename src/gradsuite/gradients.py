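"""Diffusion-map connectivity gradients.

A functional gradient is a continuous axis ordering regions by similarity
of their connectivity profiles. The pipeline is the standard one used for
cortical gradient mapping:

1. **Column sparsification** — keep, per column, the strongest
   ``retain`` fraction of entries by signed value (default 10%), zeroing
   the rest; strong negative correlations are thereby dropped.
2. **Normalized-angle affinity** — similarity between row pairs,
   ``A_ij = 1 − arccos(cos(row_i, row_j))/π``, mapping cosine similarity
   from [−1, 1] to [0, 1].
3. **Diffusion-map embedding** — anisotropic normalization
   ``W = A / (d_i^α d_j^α)`` with α = 0.5, row-stochastic transition matrix
   ``P = D⁻¹W``, eigendecomposition via the symmetric conjugate, trivial
   constant eigenvector dropped, and components scaled by ``λ/(1−λ)``
   (diffusion time 0) or ``λ^t``.
4. **Procrustes alignment** — orthogonal rotation onto a template
   embedding, resolving the rotation/sign indeterminacy of eigenvectors so
   groups and subjects are comparable.

Downstream summaries: explained-variance ratios (scaled eigenvalues),
gradient range (max − min score), endpoint parcels, per-network means.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh, orthogonal_procrustes

from .exceptions import ContractError, DegenerateDataError
from .parcellation import NETWORKS, ParcellationScheme

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    """Diffusion-map embedding parameters.

    n_components: gradients to retain (10 whole-brain, 3 for the insula).
    alpha: anisotropic diffusion exponent in [0, 1]; 0.5 normalizes away
        sampling-density effects (Fokker–Planck diffusion).
    diffusion_time: 0 selects the multi-scale λ/(1−λ) weighting; t > 0
        weights components by λ^t.
    sparsity: fraction of entries retained per column before the affinity.
    random_seed: recorded for provenance; the dense symmetric eigensolver
        used here is deterministic, so it does not influence results.
    """

    n_components: int = 10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    sparsity: float = 0.10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ContractError("n_components must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ContractError("alpha must be in [0, 1]")
        if self.diffusion_time < 0:
            raise ContractError("diffusion_time must be >= 0")


INSULA_COMPONENTS = 3  # default gradient count for 17-parcel insula embeddings


@dataclass
class GradientSet:
    """Embedding result: N×k scores, eigenvalues, variance ratios.

    ``eigenvalues`` are the non-trivial transition-matrix eigenvalues in
    non-increasing order; ``explained_variance`` scales them to sum to 1
    over the retained components. ``degenerate`` marks embeddings of
    structureless (all-equal) affinities, whose scores are all zero.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    aligned_to: str | None = None
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def sparsify_columns(M: np.ndarray, retain: float = 0.10) -> np.ndarray:
    """Keep the ceil(retain·N) largest entries of each column (signed value).

    Ties are broken toward the lowest row index. ceil() guarantees at least
    one survivor per column. The output is generally asymmetric even for
    symmetric input.
    """
    if retain <= 0:
        raise ContractError("retain fraction must be > 0")
    M = np.asarray(M, dtype=float)
    if retain >= 1.0:
        return M.copy()
    n_keep = math.ceil(retain * M.shape[0])
    # stable argsort on -value => ties resolved toward lower row index
    order = np.argsort(-M, axis=0, kind="stable")
    out = np.zeros_like(M)
    rows = order[:n_keep, :]
    cols = np.broadcast_to(np.arange(M.shape[1]), rows.shape)
    out[rows, cols] = M[rows, cols]
    return out


def normalized_angle_affinity(M: np.ndarray) -> np.ndarray:
    """Normalized-angle similarity between all row pairs of M.

    ``A_ij = 1 − arccos(clip(cosine(row_i, row_j), ±1))/π`` — symmetric,
    entries in [0, 1], unit diagonal. Zero rows have no direction and raise
    :class:`DegenerateDataError`.
    """
    M = np.asarray(M, dtype=float)
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms == 0):
        raise DegenerateDataError(
            f"zero rows at indices {np.flatnonzero(norms == 0).tolist()}; "
            "cannot form angles")
    cos = (M @ M.T) / np.outer(norms, norms)
    A = 1.0 - np.arccos(np.clip(cos, -1.0, 1.0)) / np.pi
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


def _check_affinity(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ContractError("affinity must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ContractError("affinity must be symmetric")
    if A.min() < -1e-12:
        raise ContractError("affinity must be non-negative")
    return (A + A.T) / 2.0


def diffusion_map_embedding(A: np.ndarray, cfg: EmbeddingConfig) -> GradientSet:
    """Embed an affinity matrix by anisotropic diffusion maps.

    Eigendecomposition runs on the symmetric conjugate
    ``S = D̃^{-1/2} W̃ D̃^{-1/2}`` of the transition matrix for numerical
    stability; eigenvectors are mapped back and normalized by the trivial
    stationary eigenvector, which is then dropped. Components are ordered
    by non-increasing eigenvalue.
    """
    A = _check_affinity(A)
    N = A.shape[0]
    if cfg.n_components > N - 1:
        raise ContractError(f"n_components={cfg.n_components} too large for N={N}")

    d = A.sum(axis=1)
    if np.any(d == 0):
        raise DegenerateDataError("affinity has an isolated (zero-degree) node")
    W = A / np.outer(d ** cfg.alpha, d ** cfg.alpha)
    d2 = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d2)
    S = W * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    evals, evecs = eigh(S)          # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]
    # map back to right eigenvectors of P = D̃^{-1} W̃ and normalize by the
    # trivial (constant) eigenvector; for a connected graph that vector is
    # sqrt(d̃)/‖sqrt(d̃)‖, so the division reduces to a scalar — which also
    # stays finite when near-disconnected inputs make the eigenvalue-1
    # eigenspace degenerate
    psi = evecs * (inv_sqrt[:, None] * np.linalg.norm(np.sqrt(d2)))
    # clip away numerical noise: λ of a stochastic matrix lies in (-1, 1];
    # λ = 1 beyond the trivial one signals a disconnected graph and would
    # blow up the λ/(1−λ) weighting, so bound it just below 1
    lam = np.clip(evals[1:cfg.n_components + 1], 0.0, 1.0 - 1e-12)
    vec = psi[:, 1:cfg.n_components + 1]

    if np.allclose(lam, 0.0, atol=1e-10):
        logger.warning("degenerate affinity: all non-trivial eigenvalues ~0")
        k = cfg.n_components
        return GradientSet(np.zeros((N, k)), np.zeros(k), np.zeros(k),
                           degenerate=True)

    if cfg.diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam ** cfg.diffusion_time
    scores = vec * scale
    # reproducible sign convention pre-alignment: first row non-negative
    flip = np.where(scores[0, :] < 0, -1.0, 1.0)
    scores = scores * flip
    return GradientSet(scores, lam.copy(), explained_variance(lam))


def explained_variance(eigenvalues: np.ndarray) -> np.ndarray:
    """Scaled eigenvalues: each λ over the sum of the retained λ."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ContractError("eigenvalues must be non-negative")
    total = lam.sum()
    if total == 0:
        raise DegenerateDataError("all eigenvalues zero")
    return lam / total


def procrustes_align(source: GradientSet, template: GradientSet,
                     template_id: str = "template") -> GradientSet:
    """Rotate source scores onto the template (orthogonal Procrustes).

    No centering or scaling — a pure rotation/reflection minimizing
    ‖source·R − template‖_F, followed by a per-column sign flip enforcing
    non-negative correlation with the template gradient. Eigenvalues and
    variance ratios are unchanged.
    """
    s, t = source.scores, template.scores
    if s.shape != t.shape:
        raise ContractError(f"shape mismatch {s.shape} vs {t.shape}")
    R, _ = orthogonal_procrustes(s, t)
    aligned = s @ R
    for k in range(aligned.shape[1]):
        if aligned[:, k].std() > 0 and t[:, k].std() > 0:
            if np.corrcoef(aligned[:, k], t[:, k])[0, 1] < 0:
                aligned[:, k] = -aligned[:, k]
    return replace(source, scores=aligned, aligned_to=template_id)


def compute_gradients(matrix: np.ndarray, cfg: EmbeddingConfig,
                      template: GradientSet | None = None,
                      template_id: str = "template") -> GradientSet:
    """Full gradient pipeline for one connectivity matrix.

    Each region's connectivity profile (row) is thresholded to its
    strongest 10% of entries, the normalized-angle affinity is computed
    between all row pairs, the affinity is embedded by diffusion maps and
    (optionally) Procrustes-aligned to a template. Profile thresholding is
    implemented by applying the column sparsifier to the transpose, the
    convention of the reference gradient toolboxes: every region retains
    the same number of connections, so no profile can be emptied by
    competition within a target's column.
    """
    matrix = np.asarray(matrix, dtype=float)
    sparse = sparsify_columns(matrix.T, cfg.sparsity).T
    A = normalized_angle_affinity(sparse)
    gs = diffusion_map_embedding(A, cfg)
    if template is not None and not gs.degenerate:
        gs = procrustes_align(gs, template, template_id)
    return gs


# ---------------------------------------------------------------------------
# summaries

def gradient_range(scores_column: np.ndarray) -> float:
    """max − min of a gradient score vector (the compression statistic)."""
    v = np.asarray(scores_column, dtype=float).ravel()
    if v.size < 2:
        raise ContractError("need at least 2 scores for a range")
    return float(v.max() - v.min())


def endpoint_parcels(scores_column: np.ndarray, scheme: ParcellationScheme,
                     parcel_indices: np.ndarray | None = None,
                     ) -> tuple[dict, dict]:
    """Identify the parcels at the two gradient endpoints.

    ``parcel_indices`` gives the 0-based scheme indices of the scored subset
    (defaults to all parcels). Ties resolve to the lowest parcel id with a
    logged warning. Returns (min_endpoint, max_endpoint) dicts with label
    and subdivision.
    """
    v = np.asarray(scores_column, dtype=float).ravel()
    idx = (np.arange(scheme.n_parcels) if parcel_indices is None
           else np.asarray(parcel_indices))
    if v.size != idx.size:
        raise ContractError("scores length does not match parcel subset")
    if np.ptp(v) == 0:
        logger.warning("all-equal gradient scores: endpoints tied, "
                       "reporting first parcel for both")
    lo, hi = int(np.argmin(v)), int(np.argmax(v))  # argmin/argmax: first hit on ties

    def _info(pos: int) -> dict:
        row = scheme.table.iloc[idx[pos]]
        return {"parcel_id": int(row["parcel_id"]), "label": row["label"],
                "subdivision": row.get("insula_subdivision", "unassigned"),
                "score": float(v[pos])}

    return _info(lo), _info(hi)


def network_mean_scores(scores_column: np.ndarray, scheme: ParcellationScheme,
                        ) -> pd.DataFrame:
    """Per-network mean and SEM of parcel gradient scores."""
    v = np.asarray(scores_column, dtype=float).ravel()
    if v.size != scheme.n_parcels:
        raise ContractError("scores length does not match parcellation")
    rows = []
    for net in NETWORKS:
        sel = v[scheme.network_indices(net)]
        if sel.size == 0:
            raise DegenerateDataError(f"network {net} has no parcels")
        sem = float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else 0.0
        rows.append({"network": net, "mean": float(sel.mean()),
                     "sem": sem, "n_parcels": int(sel.size)})
    return pd.DataFrame(rows)
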