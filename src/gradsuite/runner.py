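"""End-to-end analysis runner and report writer.

Executes the study pipeline on an on-disk layout (parcellation table,
per-subject connectivity matrices, subject table):

1. healthy-control group average → whole-brain template gradients;
2. per-subject whole-brain gradients, Procrustes-aligned to the template,
   with alignment QC (subjects whose aligned principal gradient correlates
   with the template below ``min_template_r`` are excluded);
3. group-average gradients and the insula sub-gradient bundles (whole
   brain + seven networks), aligned to the control template bundle;
4. group statistics: parcel-wise ANCOVA with FDR, gradient-range and
   explained-variance t-tests, 2×R and 2×7×R mixed ANOVAs with Bonferroni
   cell contrasts, network means, endpoint subdivisions,
   anterior–posterior separation, and HAM-D correlations per network with
   the Fisher r-to-z group comparison;
5. a run directory of CSV tables, a plain-text summary and the resolved
   configuration.

The computation is split into :func:`compute_gradient_state` (stages 1–3)
and :func:`compute_statistics` (stage 4) so the CLI can run each stage
separately; all stages are deterministic functions of the inputs and the
config.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .exceptions import DegenerateDataError, GradsuiteError
from .fc import alignment_qc, group_average
from .gradients import (EmbeddingConfig, GradientSet, compute_gradients,
                        gradient_range, network_mean_scores)
from .insula import (TARGETS, SubgradientBundle, anterior_posterior_separation,
                     endpoint_subdivisions, run_insula_pipeline)
from .io import read_cohort, read_matrix, write_matrix
from .parcellation import ParcellationScheme, read_parcellation, read_subdivision_table
from .stats import (fisher_rz_compare, mixed_anova, parcelwise_ancova,
                    pearson_with_hamd, range_ttest, results_table)

logger = logging.getLogger(__name__)


def validate_inputs(cfg: RunConfig, base: str | Path = ".") -> list[str]:
    """Check the on-disk layout; returns a list of failure messages
    (empty = valid). Never mutates inputs."""
    base = Path(base)
    failures: list[str] = []
    parc = base / cfg.parcellation
    if not parc.exists():
        return [f"parcellation file missing: {parc}"]
    try:
        scheme = read_parcellation(parc, insula_pattern=cfg.insula_pattern)
    except GradsuiteError as e:
        return [f"parcellation unreadable: {e}"]
    if scheme.insula_indices().size == 0:
        failures.append("no insula parcels match the configured pattern")
    table = base / cfg.subject_table
    if not table.exists():
        return failures + [f"subject table missing: {table}"]
    try:
        cohort = read_cohort(table)
    except GradsuiteError as e:
        return failures + [f"subject table unreadable: {e}"]
    P = scheme.n_parcels
    for sid in cohort["subject_id"]:
        f = base / cfg.matrices_dir / f"{sid}_fc.tsv"
        if not f.exists():
            failures.append(f"matrix file missing for subject {sid}")
            continue
        M = read_matrix(f)
        if M.shape != (P, P):
            failures.append(f"{sid}: matrix shape {M.shape}, expected ({P}, {P})")
    return failures


@dataclass
class GradientState:
    """Everything stages 1–3 produce (inputs to the statistics stage)."""

    scheme: ParcellationScheme
    cohort: pd.DataFrame             # analyzed subjects (post-QC)
    qc: pd.DataFrame                 # per-subject template r / inclusion
    n_excluded: int
    template: GradientSet
    subject_wb: list[GradientSet]    # post-QC, cohort order
    group_wb: dict[str, GradientSet]
    insula_template: SubgradientBundle
    group_bundles: dict[str, SubgradientBundle]
    subject_bundles: list[SubgradientBundle]


def compute_gradient_state(cfg: RunConfig, base: str | Path = ".") -> GradientState:
    """Stages 1–3: load inputs, embed, align, QC."""
    base = Path(base)
    failures = validate_inputs(cfg, base)
    if failures:
        raise GradsuiteError("input validation failed: " + "; ".join(failures))
    scheme = read_parcellation(base / cfg.parcellation,
                               insula_pattern=cfg.insula_pattern)
    if cfg.subdivisions and (base / cfg.subdivisions).exists():
        scheme.apply_subdivisions(read_subdivision_table(base / cfg.subdivisions))
    cohort = read_cohort(base / cfg.subject_table)
    matrices = [read_matrix(base / cfg.matrices_dir / f"{sid}_fc.tsv")
                for sid in cohort["subject_id"]]
    logger.info("loaded %d subjects, %d parcels, %d insula parcels",
                len(cohort), scheme.n_parcels, scheme.insula_indices().size)

    emb = cfg.embedding
    wb_cfg = EmbeddingConfig(n_components=emb.n_components_whole_brain,
                             alpha=emb.alpha, diffusion_time=emb.diffusion_time,
                             sparsity=emb.sparsity, random_seed=cfg.seed)
    ins_cfg = EmbeddingConfig(n_components=emb.n_components_insula,
                              alpha=emb.alpha, diffusion_time=emb.diffusion_time,
                              sparsity=emb.sparsity, random_seed=cfg.seed)
    groups = cohort["group"].to_numpy()

    hc_mats = [m for m, g in zip(matrices, groups) if g == "HC"]
    template = compute_gradients(group_average(hc_mats), wb_cfg)
    subj_wb, qc_rows = [], []
    for sid, M in zip(cohort["subject_id"], matrices):
        gs = compute_gradients(M, wb_cfg, template=template, template_id="HC")
        r, ok = alignment_qc(gs.scores[:, 0], template.scores[:, 0],
                             min_r=cfg.qc.min_template_r)
        qc_rows.append({"subject_id": sid, "template_r": r, "included": ok})
        subj_wb.append(gs)
    qc = pd.DataFrame(qc_rows)
    included = qc["included"].to_numpy()
    n_excluded = int((~included).sum())
    if n_excluded:
        logger.warning("alignment QC excluded %d subject(s): %s", n_excluded,
                       qc.loc[~qc["included"], "subject_id"].tolist())
    cohort_i = cohort.loc[included].reset_index(drop=True)
    groups_i = cohort_i["group"].to_numpy()
    mats_i = [m for m, ok in zip(matrices, included) if ok]
    wb_i = [g for g, ok in zip(subj_wb, included) if ok]
    if (groups_i == "HC").sum() < 2 or (groups_i == "MDD").sum() < 2:
        raise DegenerateDataError("fewer than 2 subjects per group after QC")

    hc_mean = group_average([m for m, g in zip(mats_i, groups_i) if g == "HC"])
    mdd_mean = group_average([m for m, g in zip(mats_i, groups_i) if g == "MDD"])
    group_wb = {g: compute_gradients(m, wb_cfg, template=template,
                                     template_id="HC")
                for g, m in (("HC", hc_mean), ("MDD", mdd_mean))}
    ins_template = run_insula_pipeline(hc_mean, scheme, ins_cfg)
    group_bundles = {g: run_insula_pipeline(m, scheme, ins_cfg,
                                            template=ins_template)
                     for g, m in (("HC", hc_mean), ("MDD", mdd_mean))}
    subj_bundles = [run_insula_pipeline(m, scheme, ins_cfg,
                                        template=ins_template)
                    for m in mats_i]
    logger.info("gradient stage complete: %d analyzed subjects, "
                "%d insula targets", len(cohort_i), len(TARGETS))
    return GradientState(scheme, cohort_i, qc, n_excluded, template, wb_i,
                         group_wb, ins_template, group_bundles, subj_bundles)


def compute_statistics(state: GradientState,
                       cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Stage 4: all group inference and descriptive summaries."""
    scheme, cohort = state.scheme, state.cohort
    groups = cohort["group"].to_numpy()
    mdd = groups == "MDD"
    out: dict[str, pd.DataFrame] = {}

    wb_scores = np.stack([g.scores[:, 0] for g in state.subject_wb])
    out["parcelwise_ancova"] = results_table(
        parcelwise_ancova(wb_scores, cohort, labels=list(scheme.labels)))

    wb_ranges = np.array([gradient_range(s) for s in wb_scores])
    ev1 = np.array([g.explained_variance[0] for g in state.subject_wb])
    ins_wb = np.stack([b["whole_brain"].scores[:, 0]
                       for b in state.subject_bundles])
    ins_ranges = np.array([gradient_range(s) for s in ins_wb])
    ins_ev1 = np.array([b["whole_brain"].explained_variance[0]
                        for b in state.subject_bundles])
    out["two_sample_tests"] = results_table([
        range_ttest(wb_ranges[mdd], wb_ranges[~mdd],
                    "whole_brain_gradient1_range"),
        range_ttest(ev1[mdd], ev1[~mdd], "whole_brain_explained_variance_1"),
        range_ttest(ins_ranges[mdd], ins_ranges[~mdd],
                    "insula_whole_brain_gradient1_range"),
        range_ttest(ins_ev1[mdd], ins_ev1[~mdd],
                    "insula_whole_brain_explained_variance_1"),
    ])

    region_labels = scheme.insula_table()["label"].tolist()
    long_rows = []
    for (_, subj), bundle in zip(cohort.iterrows(), state.subject_bundles):
        for target in TARGETS:
            scores = bundle[target].scores[:, 0]
            for r_idx, lab in enumerate(region_labels):
                long_rows.append({
                    "subject_id": subj["subject_id"], "group": subj["group"],
                    "age": subj["age"], "gender": subj["gender"],
                    "target": target, "region": lab, "score": scores[r_idx]})
    long = pd.DataFrame(long_rows)
    out["mixed_anova_2x17"] = results_table(mixed_anova(
        long[long["target"] == "whole_brain"], within="region",
        family_size=cfg.stats.family_size_regions))
    out["mixed_anova_2x7x17"] = results_table(mixed_anova(
        long[long["target"] != "whole_brain"].rename(columns={"target": "network"}),
        within=["network", "region"],
        family_size=cfg.stats.family_size_network_regions))

    corr_rows = []
    for target in TARGETS:
        means = np.array([b[target].scores[:, 0].mean()
                          for b in state.subject_bundles])
        res = {}
        for g in ("MDD", "HC"):
            sel = groups == g
            try:
                res[g] = pearson_with_hamd(means[sel],
                                           cohort.loc[sel, "hamd"].to_numpy())
            except DegenerateDataError:
                res[g] = None
        row: dict = {"target": target}
        for g in ("MDD", "HC"):
            row[f"r_{g}"] = res[g].r if res[g] else np.nan
            row[f"p_{g}"] = res[g].p if res[g] else np.nan
            row[f"n_{g}"] = res[g].n if res[g] else 0
        if res["MDD"] and res["HC"]:
            z, p = fisher_rz_compare(res["MDD"].r, res["MDD"].n,
                                     res["HC"].r, res["HC"].n,
                                     one_sided=cfg.stats.tails == "one-sided")
            row["fisher_z"], row["fisher_p"] = z, p
        corr_rows.append(row)
    out["hamd_correlations"] = pd.DataFrame(corr_rows)

    out["network_means"] = pd.concat(
        [network_mean_scores(state.group_wb[g].scores[:, 0], scheme).assign(group=g)
         for g in ("HC", "MDD")], ignore_index=True)
    out["endpoint_subdivisions"] = pd.concat(
        [endpoint_subdivisions(state.group_bundles[g], scheme).assign(group=g)
         for g in ("HC", "MDD")], ignore_index=True)
    sep_rows = []
    for g in ("HC", "MDD"):
        for target in TARGETS:
            try:
                sep = anterior_posterior_separation(
                    state.group_bundles[g][target].scores[:, 0], scheme)
                sep_rows.append({"group": g, "target": target, "d": sep.d,
                                 "degenerate": sep.degenerate})
            except DegenerateDataError as e:
                sep_rows.append({"group": g, "target": target, "d": np.nan,
                                 "degenerate": True})
                logger.warning("separation undefined for %s/%s: %s", g, target, e)
    out["ap_separation"] = pd.DataFrame(sep_rows)
    return out


# ---------------------------------------------------------------------------
# stage writers

def write_gradient_outputs(state: GradientState, cfg: RunConfig,
                           out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    state.qc.to_csv(out / "alignment_qc.csv", index=False)
    for g in ("HC", "MDD"):
        gs = state.group_wb[g]
        write_matrix(gs.scores, out / f"{g}_whole_brain_gradients.tsv")
        pd.DataFrame({
            "component": np.arange(1, gs.n_components + 1),
            "eigenvalue": gs.eigenvalues,
            "explained_variance": gs.explained_variance,
        }).to_csv(out / f"{g}_whole_brain_variance.csv", index=False)


def write_insula_outputs(state: GradientState, cfg: RunConfig,
                         out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {}
    for g in ("HC", "MDD"):
        for target in TARGETS:
            gs = state.group_bundles[g][target]
            write_matrix(gs.scores, out / f"{g}_insula_{target}_gradients.tsv")
            sidecar[f"{g}:{target}"] = {
                "eigenvalues": gs.eigenvalues.tolist(),
                "explained_variance": gs.explained_variance.tolist(),
                "gradient1_range": gradient_range(gs.scores[:, 0]),
            }
    (out / "insula_bundles.json").write_text(json.dumps(sidecar, indent=2))


def write_stats_outputs(stats: dict[str, pd.DataFrame], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name, df in stats.items():
        df.to_csv(out / f"{name}.csv", index=False)


def run_full_analysis(cfg: RunConfig, base: str | Path = ".") -> Path:
    """Run every stage and write the complete run directory."""
    base = Path(base)
    out = base / cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gradsuite")
    root.addHandler(fh)
    try:
        state = compute_gradient_state(cfg, base)
        stats = compute_statistics(state, cfg)
        write_gradient_outputs(state, cfg, out)
        write_insula_outputs(state, cfg, out)
        write_stats_outputs(stats, out)
        cfg.to_yaml(out / "resolved_config.yaml")
        (out / "summary.txt").write_text(write_report(state, stats))
        (out / "summary.json").write_text(json.dumps(
            summary_numbers(state, stats), indent=2))
        logger.info("run complete: %s", out)
    finally:
        root.removeHandler(fh)
    return out


def summary_numbers(state: GradientState,
                    stats: dict[str, pd.DataFrame]) -> dict:
    groups = state.cohort["group"].to_numpy()
    mdd = groups == "MDD"
    wb_ranges = np.array([gradient_range(g.scores[:, 0])
                          for g in state.subject_wb])
    ins_ranges = np.array([gradient_range(b["whole_brain"].scores[:, 0])
                           for b in state.subject_bundles])
    return {
        "whole_brain_ev1": {g: float(state.group_wb[g].explained_variance[0])
                            for g in ("HC", "MDD")},
        "insula_whole_brain_ev1": {
            g: float(state.group_bundles[g]["whole_brain"].explained_variance[0])
            for g in ("HC", "MDD")},
        "whole_brain_range_subject_mean": {
            "HC": float(wb_ranges[~mdd].mean()),
            "MDD": float(wb_ranges[mdd].mean())},
        "insula_whole_brain_range_subject_mean": {
            "HC": float(ins_ranges[~mdd].mean()),
            "MDD": float(ins_ranges[mdd].mean())},
        "n_analyzed": int(len(state.cohort)),
        "n_excluded": state.n_excluded,
        "n_insula_targets": len(TARGETS),
    }


def write_report(state: GradientState, stats: dict[str, pd.DataFrame]) -> str:
    cohort = state.cohort
    lines = [
        "gradsuite run summary",
        "=====================",
        f"subjects analyzed: {len(cohort)} "
        f"({(cohort['group'] == 'MDD').sum()} MDD / "
        f"{(cohort['group'] == 'HC').sum()} HC); "
        f"{state.n_excluded} excluded by alignment QC",
        "",
        "whole-brain principal gradient",
    ]
    for g in ("HC", "MDD"):
        gs = state.group_wb[g]
        lines.append(f"  {g}: explained variance " +
                     ", ".join(f"g{i + 1}={v:.3f}"
                               for i, v in enumerate(gs.explained_variance)))
        lines.append(f"  {g}: gradient-1 range (group mean matrix) "
                     f"{gradient_range(gs.scores[:, 0]):.4f}")
    lines.append("")
    lines.append("insula sub-gradients (8 targets; gradient-1 explained variance)")
    for g in ("HC", "MDD"):
        lines.append("  " + g + ": " + ", ".join(
            f"{t}={state.group_bundles[g][t].explained_variance[0]:.3f}"
            for t in TARGETS))
    lines.append("")
    lines.append("group tests (pooled-variance t):")
    for _, row in stats["two_sample_tests"].iterrows():
        lines.append(f"  {row['effect']}: t({int(row['df1'])}) = "
                     f"{row['statistic']:.3f}, p = {row['p_raw']:.3f}")
    corr = stats["hamd_correlations"]
    dan = corr[corr["target"] == "DAN"].iloc[0]
    lines.append("")
    lines.append("insula-DAN mean gradient vs HAM-D: "
                 f"MDD r = {dan['r_MDD']:.3f} (n={int(dan['n_MDD'])}), "
                 f"HC r = {dan['r_HC']:.3f} (n={int(dan['n_HC'])}), "
                 f"Fisher z = {dan.get('fisher_z', float('nan')):.3f}")
    return "\n".join(lines) + "\n"
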