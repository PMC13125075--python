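"""Group inference for gradient scores.

Implements the full comparison layer between a patient-like and a control
group:

* parcel-wise ANCOVA (linear model ``score ~ group + age + gender``) with
  Benjamini–Hochberg FDR across parcels;
* mixed-design (split-plot) ANOVA with one between-subject factor (group),
  one or two within-subject factors (insula region, network), and
  age/gender covariates, with per-cell Bonferroni-corrected group
  contrasts and optional Greenhouse–Geisser-corrected p values;
* two-sample pooled-variance t-tests for gradient ranges and
  explained-variance ratios;
* Pearson correlations with symptom scores (HAM-D) and Fisher r-to-z
  comparison of correlations between independent groups.

The mixed ANOVA uses the classical multi-stratum decomposition: the
between-subjects stratum is an ANCOVA on subject means; each within
stratum regresses subject-demeaned cell means on sum-coded factor,
group-by-factor, and covariate-by-factor terms, with the subject-by-factor
interaction as the error term. Balanced within-subject structure (every
subject observed in every cell) is required.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ContractError, DegenerateDataError


@dataclass
class StatResult:
    """One inferential effect: statistic, df, raw/corrected p, effect size."""

    effect_name: str
    statistic: float            # t or F
    df: tuple[float, float]
    p_raw: float
    p_corrected: float
    correction: str             # none | FDR_BH | bonferroni
    effect_size: float          # partial eta squared, or mean difference
    ci95: tuple[float, float] | None = None
    mean_difference: float | None = None
    p_gg: float | None = None   # Greenhouse-Geisser corrected, when defined


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    z_fisher: float


# ---------------------------------------------------------------------------
# multiple-comparison corrections

def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ContractError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bonferroni(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, p·m); m defaults to the vector length."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ContractError("family size m smaller than number of tests")
    return np.minimum(p * m, 1.0)


# ---------------------------------------------------------------------------
# parcel-wise ANCOVA

def _group_indicator(groups: pd.Series | np.ndarray) -> np.ndarray:
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ContractError(f"need exactly 2 groups, got {list(levels)}")
    # MDD coded 1 and HC 0 when present, so mean differences read MDD−HC
    if set(levels) == {"MDD", "HC"}:
        return (g == "MDD").astype(float)
    return (g == levels[0]).astype(float)


def _covariate_matrix(cohort: pd.DataFrame) -> np.ndarray:
    age = cohort["age"].to_numpy(dtype=float)
    gender = cohort["gender"]
    if gender.dtype == object:
        gender = (gender == "F").astype(float)
    return np.column_stack([age, np.asarray(gender, dtype=float)])


def _ancova_f(y: np.ndarray, g: np.ndarray, cov: np.ndarray,
              ) -> tuple[np.ndarray, ...]:
    """Vectorized ANCOVA of each column of y on [1 | g | cov].

    Returns (F, p, eta2p, diff, lo, hi, df) for the group effect, where diff
    is the adjusted group-1 minus group-0 mean difference with its 95% CI.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    cov = np.asarray(cov, dtype=float)
    cov = cov[:, cov.std(axis=0) > 0]  # constant covariates carry no information
    X = np.column_stack([np.ones(n), g, cov])
    X0 = np.column_stack([np.ones(n), cov])
    p_full = X.shape[1]
    df_err = n - p_full
    if df_err <= 0:
        raise ContractError("not enough subjects for the ANCOVA design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_f = np.sum((y - X @ beta) ** 2, axis=0)
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss_r = np.sum((y - X0 @ beta0) ** 2, axis=0)
    ss_g = np.maximum(rss_r - rss_f, 0.0)
    mse = rss_f / df_err
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(mse > 0, ss_g / mse, 0.0)
        eta2p = np.where(ss_g + rss_f > 0, ss_g / (ss_g + rss_f), 0.0)
    p = sps.f.sf(F, 1, df_err)
    diff = beta[1, :]
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(mse, 0) * xtx_inv[1, 1])
    tcrit = sps.t.ppf(0.975, df_err)
    return F, p, eta2p, diff, diff - tcrit * se, diff + tcrit * se, df_err


def parcelwise_ancova(scores: np.ndarray, cohort: pd.DataFrame,
                      labels: list[str] | None = None) -> list[StatResult]:
    """Covariate-adjusted group comparison at every parcel, FDR-corrected.

    ``scores`` is subjects × parcels (rows aligned with ``cohort``); each
    parcel gets a linear model ``score ~ group + age + gender`` with the F
    test of the group effect, Benjamini–Hochberg correction running across
    all parcels.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(cohort):
        raise ContractError("scores rows must match cohort rows")
    g = _group_indicator(cohort["group"])
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ContractError("need at least 2 subjects per group")
    cov = _covariate_matrix(cohort)
    F, p, eta2p, diff, lo, hi, df_err = _ancova_f(scores, g, cov)
    p_adj = bh_fdr(p)
    names = labels if labels is not None else [f"parcel_{i + 1}"
                                               for i in range(scores.shape[1])]
    return [StatResult(names[j], float(F[j]), (1.0, float(df_err)),
                       float(p[j]), float(p_adj[j]), "FDR_BH",
                       float(eta2p[j]), (float(lo[j]), float(hi[j])),
                       mean_difference=float(diff[j]))
            for j in range(scores.shape[1])]


# ---------------------------------------------------------------------------
# mixed-design (split-plot) ANOVA

def _sum_code(values: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding; returns (n × (L−1) matrix, levels)."""
    levels = list(pd.unique(values))
    L = len(levels)
    idx = pd.Categorical(values, categories=levels).codes
    Z = np.zeros((len(values), L - 1))
    for k in range(L - 1):
        Z[idx == k, k] = 1.0
    Z[idx == L - 1, :] = -1.0
    return Z, levels


def _stratum_tests(d: np.ndarray, factor_codes: np.ndarray, g_pm: np.ndarray,
                   cov_c: np.ndarray, df_eff_base: int, n_sub: int,
                   effect_prefix: str) -> list[tuple[str, float, float, float, float]]:
    """F tests inside one within-subject stratum.

    ``d`` are the stratum deviations (one per subject × stratum cell),
    ``factor_codes`` the sum-coded stratum contrast columns, ``g_pm`` the
    ±1 group code and ``cov_c`` centered covariates (per observation).
    Returns (name, F, df1, df2, eta2p, ...) tuples for the factor main
    effect and the group×factor interaction.
    """
    Za = factor_codes
    blocks = {
        effect_prefix: Za,
        f"group:{effect_prefix}": Za * g_pm[:, None],
    }
    cov_blocks = [Za * cov_c[:, [j]] for j in range(cov_c.shape[1])]
    X_full = np.hstack(list(blocks.values()) + cov_blocks)
    rss_full = _rss(X_full, d)
    n_cov = cov_c.shape[1]
    df_err = df_eff_base * (n_sub - 2 - n_cov)  # 2 group levels
    if df_err <= 0:
        raise ContractError("not enough subjects for the within stratum")
    out = []
    for name, block in blocks.items():
        others = [b for nm, b in blocks.items() if nm != name] + cov_blocks
        rss_red = _rss(np.hstack(others), d)
        ss = max(rss_red - rss_full, 0.0)
        df1 = block.shape[1]
        mse = rss_full / df_err
        F = ss / df1 / mse if mse > 0 else 0.0
        eta2p = ss / (ss + rss_full) if ss + rss_full > 0 else 0.0
        out.append((name, F, float(df1), float(df_err), eta2p))
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


def _gg_epsilon(cells: np.ndarray, groups: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance of
    the cell scores, under the contrast matrix C (rows = contrasts)."""
    resid = cells - np.vstack([cells[groups == lev].mean(axis=0)
                               for lev in groups])  # per-row group mean
    S = resid.T @ resid / max(len(cells) - len(np.unique(groups)), 1)
    M = C @ S @ C.T
    tr = np.trace(M)
    denom = M.shape[0] * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    return float(min(max(tr ** 2 / denom, 1.0 / M.shape[0]), 1.0))


def _orth_contrasts(L: int) -> np.ndarray:
    """(L−1) × L orthonormal contrast rows spanning the mean-free space."""
    H = np.eye(L) - np.full((L, L), 1.0 / L)
    u, s, vt = np.linalg.svd(H)
    return vt[:L - 1]


def mixed_anova(long_table: pd.DataFrame, between: str = "group",
                within: list[str] | str = "region",
                covariates: tuple[str, str] = ("age", "gender"),
                subject: str = "subject_id", score: str = "score",
                family_size: int | None = None) -> list[StatResult]:
    """Split-plot ANOVA with covariates and Bonferroni cell contrasts.

    ``long_table`` is tidy: one row per subject × within-cell, with columns
    for the subject id, between-group label, covariates, each within factor
    and the score. Every subject must be observed in every within cell
    (balanced within structure); missing cells raise :class:`ContractError`
    listing the offending subjects.

    Returns StatResults for: the between-group effect (from the ANCOVA on
    subject means), each within main effect and its group interaction (with
    Greenhouse–Geisser-corrected p alongside), and one covariate-adjusted
    group contrast per within cell, Bonferroni-corrected with family size
    ``family_size`` (default: the number of cells).
    """
    if isinstance(within, str):
        within = [within]
    within = [w for w in within if long_table[w].nunique() > 1]
    df = long_table.copy()

    cell_cols = within if within else []
    if cell_cols:
        counts = df.groupby(subject, sort=False).size()
        expected = int(np.prod([df[w].nunique() for w in within]))
        bad = counts[counts != expected].index.tolist()
        if bad:
            raise ContractError(f"subjects with missing within cells: {bad}")

    # subject-level frame (means over all within cells)
    sub = df.groupby(subject, sort=False).agg(
        score=(score, "mean"), group=(between, "first"),
        age=(covariates[0], "first"), gender=(covariates[1], "first"))
    n_sub = len(sub)
    g01 = _group_indicator(sub["group"])
    cov = _covariate_matrix(sub)
    cov = cov[:, cov.std(axis=0) > 0]  # constant covariates drop out
    if long_table[score].nunique() == 1:
        raise DegenerateDataError("scores identical across all subjects/cells")

    results: list[StatResult] = []
    F, p, eta, diff, lo, hi, dfe = _ancova_f(sub["score"].to_numpy(), g01, cov)
    results.append(StatResult(between, float(F[0]), (1.0, float(dfe)),
                              float(p[0]), float(p[0]), "none", float(eta[0]),
                              (float(lo[0]), float(hi[0])),
                              mean_difference=float(diff[0])))

    # within strata
    g_pm = np.where(g01 == 1, 1.0, -1.0)
    cov_c = cov - cov.mean(axis=0)
    subj_order = sub.index.to_numpy()
    pos = {s: i for i, s in enumerate(subj_order)}
    groups_arr = sub["group"].to_numpy()

    def _cell_matrix(factors: list[str]) -> tuple[np.ndarray, list[tuple]]:
        """subjects × cells matrix of scores averaged over other factors."""
        piv = df.pivot_table(index=subject, columns=factors, values=score,
                             aggfunc="mean", sort=False)
        piv = piv.loc[subj_order]
        return piv.to_numpy(dtype=float), list(piv.columns)

    strata: list[tuple[str, list[str]]] = [(w, [w]) for w in within]
    if len(within) == 2:
        strata.append((f"{within[0]}:{within[1]}", within))

    for name, factors in strata:
        cells, cell_labels = _cell_matrix(factors)
        m = cells.shape[1]
        if name.count(":"):
            a = df[factors[0]].nunique()
            b = df[factors[1]].nunique()
            Ca, Cb = _orth_contrasts(a), _orth_contrasts(b)
            C = np.kron(Ca, Cb)
            marg_a, la = _cell_matrix([factors[0]])
            marg_b, lb = _cell_matrix([factors[1]])
            dev = (cells - cells.mean(axis=1, keepdims=True)
                   - np.repeat(marg_a - marg_a.mean(axis=1, keepdims=True), b, axis=1)
                   - np.tile(marg_b - marg_b.mean(axis=1, keepdims=True), a))
            df_eff = (a - 1) * (b - 1)
        else:
            C = _orth_contrasts(m)
            dev = cells - cells.mean(axis=1, keepdims=True)
            df_eff = m - 1
        # long-form deviations + per-observation codes
        d = dev.ravel()
        Z = np.kron(np.ones((n_sub, 1)), np.eye(m))            # cell indicator
        # sum-coded contrast columns for the stratum effect space
        Zc = Z @ C.T                                           # n_obs × df_eff
        g_rep = np.repeat(g_pm, m)
        cov_rep = np.repeat(cov_c, m, axis=0)
        tests = _stratum_tests(d, Zc, g_rep, cov_rep, df_eff, n_sub, name)
        eps = _gg_epsilon(cells, groups_arr, C)
        for eff_name, Fv, df1, df2, eta2p in tests:
            p_raw = float(sps.f.sf(Fv, df1, df2))
            p_gg = float(sps.f.sf(Fv, df1 * eps, df2 * eps))
            results.append(StatResult(eff_name, float(Fv), (df1, df2),
                                      p_raw, p_raw, "none", float(eta2p),
                                      p_gg=p_gg))

    # per-cell covariate-adjusted group contrasts, Bonferroni-corrected
    if within:
        cells, cell_labels = _cell_matrix(within)
        m = cells.shape[1]
        fam = family_size if family_size is not None else m
        F, p, eta, diff, lo, hi, dfe = _ancova_f(cells, g01, cov)
        p_adj = bonferroni(p, fam)
        for j in range(m):
            lab = cell_labels[j]
            lab = ":".join(map(str, lab)) if isinstance(lab, tuple) else str(lab)
            results.append(StatResult(f"cell[{lab}]", float(F[j]),
                                      (1.0, float(dfe)), float(p[j]),
                                      float(p_adj[j]), "bonferroni",
                                      float(eta[j]),
                                      (float(lo[j]), float(hi[j])),
                                      mean_difference=float(diff[j])))
    return results


# ---------------------------------------------------------------------------
# simple two-sample and correlation tests

def range_ttest(ranges_g1: np.ndarray, ranges_g2: np.ndarray,
                effect_name: str = "gradient_range") -> StatResult:
    """Two-sample pooled-variance t-test (df = n1 + n2 − 2)."""
    x = np.asarray(ranges_g1, dtype=float)
    y = np.asarray(ranges_g2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ContractError("need n >= 2 per group")
    n1, n2 = x.size, y.size
    dof = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / dof
    if sp2 == 0:
        raise DegenerateDataError("zero pooled variance")
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = float(x.mean() - y.mean())
    t = diff / se
    p = 2 * sps.t.sf(abs(t), dof)
    tcrit = sps.t.ppf(0.975, dof)
    return StatResult(effect_name, float(t), (float(dof), 0.0), float(p),
                      float(p), "none", diff,
                      (diff - tcrit * se, diff + tcrit * se),
                      mean_difference=diff)


def pearson_with_hamd(values: np.ndarray, hamd: np.ndarray) -> CorrelationResult:
    """Pearson correlation with a symptom score; two-sided p from the t
    reference distribution, plus the Fisher z of r."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(hamd, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ContractError("need paired samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("constant input to correlation")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), int(x.size), float(p),
                             float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))))


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int,
                      one_sided: bool = False) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's r-to-z.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); two-sided p by
    default, one-sided (in the direction of the observed difference) behind
    the flag.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ContractError("correlations must satisfy |r| < 1")
    if n1 < 4 or n2 < 4:
        raise ContractError("need n >= 4 in both groups")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = sps.norm.sf(abs(z)) if one_sided else 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def results_table(results: list[StatResult]) -> pd.DataFrame:
    """Tidy frame of StatResults (one row per effect)."""
    rows = []
    for r in results:
        rows.append({
            "effect": r.effect_name, "statistic": r.statistic,
            "df1": r.df[0], "df2": r.df[1], "p_raw": r.p_raw,
            "p_corrected": r.p_corrected, "correction": r.correction,
            "effect_size": r.effect_size,
            "mean_difference": r.mean_difference,
            "ci_low": r.ci95[0] if r.ci95 else np.nan,
            "ci_high": r.ci95[1] if r.ci95 else np.nan,
            "p_gg": r.p_gg if r.p_gg is not None else np.nan,
        })
    return pd.DataFrame(rows)
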