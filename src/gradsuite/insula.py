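"""Insula sub-gradient analyses.

The insula's connectivity hierarchy is probed by embedding the similarity
structure of insula connectivity profiles toward eight targets: the whole
brain (17×400 submatrix with the default atlas) and each of the seven
networks separately (17×D). Each submatrix goes through the same pipeline
as the whole-brain analysis (column sparsification → row-pair
normalized-angle affinity, always 17×17 → diffusion-map embedding, 3
components by default → Procrustes alignment to the healthy-control
template bundle).

Qualitative readouts of the embedding geometry are made quantitative here:
the subdivision identity of the gradient endpoints, and a standardized
anterior–posterior separation statistic
``d = |mean(anterior) − mean(posterior)| / pooled SD`` over the insula
parcels' gradient scores (anterior = vAI/dAI/dAI-frontal-operculum,
posterior = posterior).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ContractError, DegenerateDataError
from .gradients import (EmbeddingConfig, GradientSet, INSULA_COMPONENTS,
                        compute_gradients, endpoint_parcels)
from .parcellation import ANTERIOR_SUBDIVISIONS, NETWORKS, ParcellationScheme

logger = logging.getLogger(__name__)

#: embedding targets, in reporting order
TARGETS = ("whole_brain",) + NETWORKS


@dataclass
class SubgradientBundle:
    """One GradientSet per target (whole brain + 7 networks); rows are the
    insula parcels in scheme order."""

    sets: dict[str, GradientSet]
    insula_indices: np.ndarray

    def __post_init__(self) -> None:
        missing = set(TARGETS) - set(self.sets)
        if missing:
            raise ContractError(f"bundle missing targets {sorted(missing)}")

    def __getitem__(self, target: str) -> GradientSet:
        return self.sets[target]

    @property
    def n_insula(self) -> int:
        return len(self.insula_indices)


def extract_submatrix(fc: np.ndarray, scheme: ParcellationScheme,
                      target: str) -> np.ndarray:
    """Slice the insula rows of a P×P matrix against a column target.

    target = "whole_brain" keeps all P columns; a network name keeps that
    network's columns. Rows are always the insula parcels in scheme order.
    """
    fc = np.asarray(fc, dtype=float)
    ins = scheme.insula_indices()
    if ins.size == 0:
        raise ContractError("parcellation has no insula parcels")
    if target == "whole_brain":
        cols = np.arange(scheme.n_parcels)
    elif target in NETWORKS:
        cols = scheme.network_indices(target)
        if cols.size == 0:
            raise ContractError(f"target network {target} has no parcels")
    else:
        raise ContractError(f"unknown target {target!r}")
    return fc[np.ix_(ins, cols)]


def run_insula_pipeline(fc: np.ndarray, scheme: ParcellationScheme,
                        cfg: EmbeddingConfig | None = None,
                        template: SubgradientBundle | None = None,
                        ) -> SubgradientBundle:
    """Embed all eight insula submatrices of one connectivity matrix."""
    ins = scheme.insula_indices()
    if cfg is None:
        cfg = EmbeddingConfig(n_components=INSULA_COMPONENTS)
    if cfg.n_components > ins.size - 1:
        raise ContractError(f"n_components={cfg.n_components} too large for "
                            f"{ins.size} insula parcels")
    sets = {}
    for target in TARGETS:
        sub = extract_submatrix(fc, scheme, target)
        tmpl = template[target] if template is not None else None
        sets[target] = compute_gradients(sub, cfg, template=tmpl,
                                         template_id=f"HC:{target}")
    return SubgradientBundle(sets, ins)


@dataclass
class SeparationResult:
    """Standardized anterior–posterior separation of insula gradient scores."""

    d: float
    mean_anterior: float
    mean_posterior: float
    n_anterior: int
    n_posterior: int
    degenerate: bool = False  # zero pooled SD (d is inf or 0/0)


def anterior_posterior_separation(scores_column: np.ndarray,
                                  scheme: ParcellationScheme,
                                  hemisphere: str | None = None,
                                  ) -> SeparationResult:
    """Standardized separation between anterior and posterior insula scores.

    ``d = |mean(anterior) − mean(posterior)| / pooled SD``; hemisphere can
    restrict to "LH" or "RH". Perfectly separated constant groups yield
    d = inf with the degenerate flag; identical constants yield d = 0
    degenerate. Unassigned insula parcels are an error (the statistic is
    undefined without subdivision coverage).
    """
    v = np.asarray(scores_column, dtype=float).ravel()
    ins = scheme.insula_table().reset_index(drop=True)
    if v.size != len(ins):
        raise ContractError("scores length does not match insula count")
    keep = np.ones(len(ins), dtype=bool)
    if hemisphere is not None:
        if hemisphere not in ("LH", "RH"):
            raise ContractError("hemisphere must be LH or RH")
        keep = (ins["hemisphere"] == hemisphere).to_numpy()
    sub = ins["insula_subdivision"].to_numpy()
    unassigned = ins.loc[keep & (sub == "unassigned"), "label"].tolist()
    if unassigned:
        raise DegenerateDataError(
            f"insula parcels without subdivision assignment: {unassigned}")
    ant = v[keep & np.isin(sub, list(ANTERIOR_SUBDIVISIONS))]
    post = v[keep & (sub == "posterior")]
    if ant.size == 0 or post.size == 0:
        raise DegenerateDataError("need at least one anterior and one "
                                  "posterior insula parcel")
    diff = abs(float(ant.mean()) - float(post.mean()))
    va = ant.var(ddof=1) if ant.size > 1 else 0.0
    vp = post.var(ddof=1) if post.size > 1 else 0.0
    dof = ant.size + post.size - 2
    pooled = np.sqrt(((ant.size - 1) * va + (post.size - 1) * vp) / dof) if dof > 0 else 0.0
    tol = 1e-12 * max(1.0, float(np.abs(v).max()))
    if pooled <= tol:
        d = np.inf if diff > tol else 0.0
        return SeparationResult(d, float(ant.mean()), float(post.mean()),
                                ant.size, post.size, degenerate=True)
    return SeparationResult(diff / pooled, float(ant.mean()),
                            float(post.mean()), ant.size, post.size)


def endpoint_subdivisions(bundle: SubgradientBundle,
                          scheme: ParcellationScheme,
                          component: int = 0) -> pd.DataFrame:
    """Subdivision tags of both endpoints of one gradient, per target."""
    rows = []
    for target in TARGETS:
        gs = bundle[target]
        lo, hi = endpoint_parcels(gs.scores[:, component], scheme,
                                  parcel_indices=bundle.insula_indices)
        rows.append({"target": target,
                     "min_label": lo["label"], "min_subdivision": lo["subdivision"],
                     "max_label": hi["label"], "max_subdivision": hi["subdivision"]})
    return pd.DataFrame(rows)
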