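"""Group inference: corrections, ANCOVA, mixed ANOVA, correlations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gradsuite import (bh_fdr, bonferroni, fisher_rz_compare, mixed_anova,
                       parcelwise_ancova, pearson_with_hamd, range_ttest)
from gradsuite.exceptions import ContractError, DegenerateDataError
from gradsuite.stats import results_table


# ---------------------------------------------------------------------------
# multiple-comparison corrections

def test_bh_hand_example_and_constants():
    np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03])),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_fdr(np.full(7, 0.2)), 0.2)


def test_bh_matches_step_up_oracle(rng):
    """Brute-force BH definition: adjusted p_(i) = min over j >= i of
    min(1, m p_(j) / j)."""
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        m = p.size
        order = np.argsort(p)
        ranked = p[order]
        adj = np.empty(m)
        for i in range(m):
            adj[i] = min(1.0, min(m * ranked[j] / (j + 1) for j in range(i, m)))
        expected = np.empty(m)
        expected[order] = adj
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


def test_bh_rejects_invalid():
    with pytest.raises(ContractError):
        bh_fdr(np.array([0.5, 1.2]))
    with pytest.raises(ContractError):
        bh_fdr(np.array([0.5, np.nan]))


def test_bonferroni():
    np.testing.assert_allclose(bonferroni(np.array([0.01]), 17), [0.17])
    np.testing.assert_allclose(bonferroni(np.array([0.2]), 10), [1.0])
    p = np.random.default_rng(0).uniform(size=9)
    np.testing.assert_allclose(bonferroni(p, 20), np.minimum(p * 20, 1))
    with pytest.raises(ContractError):
        bonferroni(np.zeros(5), 3)


def test_corrections_monotone(rng):
    p = rng.uniform(size=30)
    order = np.argsort(p)
    for adj in (bh_fdr(p), bonferroni(p)):
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# parcel-wise ANCOVA

def test_ancova_matches_statsmodels(toy_cohort, rng):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    Y = rng.normal(size=(40, 4))
    Y[:, 2] += (toy_cohort["group"] == "MDD") * 0.8
    res = parcelwise_ancova(Y, toy_cohort)
    gender01 = (toy_cohort["gender"] == "F").astype(float)
    for j in range(4):
        d = pd.DataFrame({"y": Y[:, j],
                          "g": (toy_cohort["group"] == "MDD").astype(float),
                          "age": toy_cohort["age"], "gen": gender01})
        full = ols("y ~ g + age + gen", d).fit()
        cmp = sm.stats.anova_lm(ols("y ~ age + gen", d).fit(), full)
        assert res[j].statistic == pytest.approx(cmp["F"][1], abs=1e-9)
        assert res[j].p_raw == pytest.approx(cmp["Pr(>F)"][1], abs=1e-12)
        assert res[j].mean_difference == pytest.approx(full.params["g"], abs=1e-12)
        lo, hi = full.conf_int().loc["g"]
        assert res[j].ci95 == (pytest.approx(lo, abs=1e-9),
                               pytest.approx(hi, abs=1e-9))


def test_ancova_identical_groups_give_zero_f(toy_cohort):
    Y = np.tile(np.random.default_rng(0).normal(size=(20, 3)), (2, 1))
    cohort = toy_cohort.copy()
    cohort["age"] = np.tile(cohort["age"].to_numpy()[:20], 2)
    cohort["gender"] = np.tile(cohort["gender"].to_numpy()[:20], 2)
    res = parcelwise_ancova(Y, cohort)
    assert all(abs(r.statistic) < 1e-10 for r in res)


def test_ancova_type_one_rate_calibrated(rng):
    """Null simulation at reduced scale: empirical rate of p < 0.05 inside
    the binomial 99% interval."""
    hits, total = 0, 0
    for _ in range(60):
        n = 72
        Y = rng.normal(size=(n, 100))
        cohort = pd.DataFrame({
            "group": rng.permutation(["MDD"] * 38 + ["HC"] * 34),
            "age": rng.normal(38, 11, n),
            "gender": rng.choice(["F", "M"], n)})
        res = parcelwise_ancova(Y, cohort)
        hits += sum(r.p_raw < 0.05 for r in res)
        total += len(res)
    half = 2.576 * np.sqrt(0.05 * 0.95 / total)
    assert abs(hits / total - 0.05) < half


def test_ancova_power_planted_shift(rng):
    """1 SD group shift on 10 of 60 parcels, n=36/group: at least 80% of
    planted parcels FDR-significant (median over reps)."""
    fracs = []
    for _ in range(20):
        n = 72
        Y = rng.normal(size=(n, 60))
        g = np.array(["MDD"] * 36 + ["HC"] * 36)
        Y[g == "MDD", :10] += 1.0
        cohort = pd.DataFrame({"group": g, "age": rng.normal(38, 11, n),
                               "gender": rng.choice(["F", "M"], n)})
        res = parcelwise_ancova(Y, cohort)
        fracs.append(np.mean([res[j].p_corrected < 0.05 for j in range(10)]))
    assert np.median(fracs) >= 0.8


def test_ancova_input_contracts(toy_cohort):
    with pytest.raises(ContractError):
        parcelwise_ancova(np.zeros((40, 2)),
                          toy_cohort.assign(group="MDD"))
    with pytest.raises(ContractError):
        parcelwise_ancova(np.zeros((10, 2)), toy_cohort)


# ---------------------------------------------------------------------------
# mixed-design ANOVA

def _long(nm, nh, m=6, effect=0.0, planted_regions=(), seed=0,
          base_sd=1.0, noise_sd=1.0):
    r = np.random.default_rng(seed)
    n = nm + nh
    grp = ["MDD"] * nm + ["HC"] * nh
    base = r.normal(0, base_sd, n)
    age = r.normal(38, 11, n)
    gender = r.choice(["F", "M"], n)
    rows = []
    for i in range(n):
        for j in range(m):
            y = base[i] + 0.4 * j + r.normal(0, noise_sd)
            if grp[i] == "MDD" and j in planted_regions:
                y += effect
            rows.append({"subject_id": f"s{i}", "group": grp[i],
                         "age": age[i], "gender": gender[i],
                         "region": f"r{j:02d}", "score": y})
    return pd.DataFrame(rows)


def test_mixed_anova_matches_pingouin_balanced():
    """Covariate-free balanced design: F, p and partial eta squared for all
    three effects equal pingouin's mixed_anova."""
    import pingouin as pg
    df = _long(12, 12, seed=3)
    df["age"] = 0.0
    df["gender"] = "F"
    tab = results_table(mixed_anova(df, within="region"))
    aov = pg.mixed_anova(data=df, dv="score", within="region",
                         subject="subject_id", between="group")
    for eff, src in (("group", "group"), ("region", "region"),
                     ("group:region", "Interaction")):
        ours = tab[tab.effect == eff].iloc[0]
        ref = aov[aov.Source == src].iloc[0]
        assert ours.statistic == pytest.approx(ref.F, rel=1e-9)
        assert ours.p_raw == pytest.approx(ref.p_unc, abs=1e-12)
        assert ours.effect_size == pytest.approx(ref.np2, rel=1e-9)
        assert (ours.df1, ours.df2) == (ref.DF1, ref.DF2)


def test_mixed_anova_group_f_consistent_with_ancova():
    """Collapsing the within factor to one level reduces the mixed design
    to the plain covariate-adjusted group comparison."""
    df = _long(10, 10, m=4, seed=4)
    collapsed = (df.groupby(["subject_id", "group", "age", "gender"],
                            sort=False, as_index=False)["score"].mean())
    collapsed["region"] = "all"
    res = mixed_anova(collapsed, within="region")
    f_mixed = next(r for r in res if r.effect_name == "group")
    anc = parcelwise_ancova(collapsed[["score"]].to_numpy(),
                            collapsed.rename(columns={})[
                                ["group", "age", "gender"]].assign(
                                subject_id=collapsed["subject_id"]))
    assert f_mixed.statistic == pytest.approx(anc[0].statistic, rel=1e-9)
    assert f_mixed.p_raw == pytest.approx(anc[0].p_raw, abs=1e-12)


def test_mixed_anova_interaction_null_p_uniform():
    """No planted effects: group×region interaction p is uniform (KS)."""
    ps = []
    for rep in range(80):
        df = _long(12, 10, m=5, seed=100 + rep)
        res = mixed_anova(df, within="region")
        ps.append(next(r for r in res if r.effect_name == "group:region").p_raw)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_mixed_anova_planted_contrast_power():
    """Region-specific 1 SD shifts in 3 of 17 regions, n=36/group: flagged
    at Bonferroni 0.05 with >= 80% power."""
    hits = []
    for rep in range(20):
        df = _long(36, 36, m=17, effect=1.0, planted_regions=(0, 1, 2),
                   seed=200 + rep, base_sd=0.6, noise_sd=0.8)
        res = mixed_anova(df, within="region")
        cells = [r for r in res if r.effect_name.startswith("cell[")]
        planted = [c for c in cells
                   if c.effect_name in ("cell[r00]", "cell[r01]", "cell[r02]")]
        hits.append(np.mean([c.p_corrected < 0.05 for c in planted]))
    assert np.mean(hits) >= 0.8 - 1e-9


def test_mixed_anova_two_within_factors():
    r = np.random.default_rng(9)
    rows = []
    for i in range(16):
        grp = "MDD" if i < 8 else "HC"
        for net in ("A", "B", "C"):
            for reg in ("x", "y"):
                rows.append({"subject_id": f"s{i}", "group": grp,
                             "age": r.normal(40, 10), "gender": "F",
                             "network": net, "region": reg,
                             "score": r.normal()})
    df = pd.DataFrame(rows)
    res = mixed_anova(df, within=["network", "region"])
    names = {r.effect_name for r in res}
    assert {"group", "network", "group:network", "region", "group:region",
            "network:region", "group:network:region"} <= names
    cells = [r for r in res if r.effect_name.startswith("cell[")]
    assert len(cells) == 6  # 3 networks × 2 regions


def test_mixed_anova_degenerate_and_missing_cells():
    df = _long(4, 4, m=3, seed=1)
    df["score"] = 1.0
    with pytest.raises(DegenerateDataError):
        mixed_anova(df, within="region")
    df2 = _long(4, 4, m=3, seed=1).iloc[:-1]
    with pytest.raises(ContractError, match="missing"):
        mixed_anova(df2, within="region")


# ---------------------------------------------------------------------------
# two-sample and correlation tests

def test_range_ttest_df_and_formula(rng):
    x, y = rng.normal(0, 1, 38), rng.normal(0, 1, 34)
    res = range_ttest(x, y)
    assert res.df[0] == 70
    n1, n2 = 38, 34
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / 70
    t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    assert res.statistic == pytest.approx(t_expected, abs=1e-10)
    ref = sps.ttest_ind(x, y, equal_var=True)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_raw == pytest.approx(ref.pvalue)

    same = rng.normal(size=10)
    assert range_ttest(same, same.copy()).statistic == 0.0
    with pytest.raises(DegenerateDataError):
        range_ttest(np.ones(5), np.ones(5))


def test_pearson_perfect_and_null(rng):
    x = rng.normal(size=30)
    res = pearson_with_hamd(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    assert res.z_fisher == pytest.approx(np.arctanh(1 - 1e-15), rel=1e-3)

    ps = [pearson_with_hamd(rng.normal(size=30), rng.normal(size=30)).p
          for _ in range(300)]
    assert sps.kstest(ps, "uniform").pvalue > 0.01
    with pytest.raises(DegenerateDataError):
        pearson_with_hamd(np.ones(10), rng.normal(size=10))
    with pytest.raises(ContractError):
        pearson_with_hamd(np.arange(3.0), np.arange(3.0))


def test_fisher_rz_published_worked_example():
    """r=0.348 (n=38) vs r=0.395 (n=34) gives z = -0.22."""
    z, p = fisher_rz_compare(0.348, 38, 0.395, 34)
    assert z == pytest.approx(-0.22, abs=0.005)
    z1, p1 = fisher_rz_compare(0.348, 38, 0.395, 34, one_sided=True)
    assert p1 == pytest.approx(p / 2)


def test_fisher_rz_closed_form_and_antisymmetry():
    z, _ = fisher_rz_compare(0.5, 20, 0.0, 20)
    assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 17))
    assert fisher_rz_compare(0.3, 30, 0.3, 300)[0] == 0.0
    za, _ = fisher_rz_compare(0.1, 25, 0.6, 40)
    zb, _ = fisher_rz_compare(0.6, 40, 0.1, 25)
    assert za == pytest.approx(-zb)
    with pytest.raises(ContractError):
        fisher_rz_compare(1.0, 10, 0.5, 10)
    with pytest.raises(ContractError):
        fisher_rz_compare(0.2, 3, 0.5, 10)
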