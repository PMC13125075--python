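# gradsuite

Functional-connectivity **gradient** analysis of the insula for
case–control resting-state fMRI studies (e.g. major depressive disorder
vs healthy controls), from parcel-level connectivity matrices to group
inference.

Cortical organization can be summarized by continuous axes — *functional
gradients* — obtained by embedding the similarity structure of regional
connectivity profiles. `gradsuite` implements the full analysis chain for
a Schaefer-style 400-parcel / 7-network parcellation with 17 insula
parcels:

1. **Connectivity**: parcel BOLD series → confound residualization
   (24-parameter motion model + WM/CSF + cosine high-pass), Pearson
   correlation, Fisher r-to-z, motion flagging by FD > 0.2 mm or
   standardized DVARS > 3.
2. **Gradients**: per-profile top-10% sparsification → normalized-angle
   affinity `A_ij = 1 − arccos(cos θ_ij)/π` → anisotropic diffusion-map
   embedding (α = 0.5, λ/(1−λ) scaling) → orthogonal Procrustes alignment
   to the healthy-control template. 10 components for the whole brain,
   3 for the insula.
3. **Insula sub-gradients**: eight 17×17 affinities — insula-to-whole-brain
   (17×400) and insula-to-each-network (17×D) — embedded and aligned the
   same way.
4. **Inference**: parcel-wise ANCOVA (group + age + gender) with
   Benjamini–Hochberg FDR; 2×17 and 2×7×17 mixed-design ANOVAs with
   Bonferroni cell contrasts and Greenhouse–Geisser-corrected p values;
   pooled-variance t-tests of gradient ranges and explained-variance
   ratios; Pearson correlations of network-wise mean insula gradients with
   HAM-D and Fisher's r-to-z comparison of correlations between groups.
5. **Synthetic cohorts**: a generator that plants a 1-D
   unimodal→transmodal latent axis, an anterior–posterior insular axis, a
   group-specific loss of insular profile differentiation, and a
   controlled HAM-D↔gradient coupling — with full ground truth for
   recovery testing.

## Worked example

Simulate a study-sized cohort (38 patients / 34 controls, 400 parcels)
and run the complete analysis:

```bash
gradsuite simulate --out demo --seed 1
python - <<'PY'
from gradsuite import RunConfig
RunConfig(output_dir="run").to_yaml("demo/run.yaml")
PY
gradsuite all --config demo/run.yaml
cat demo/run/summary.txt
```

prints (abridged):

```
subjects analyzed: 72 (38 MDD / 34 HC); 0 excluded by alignment QC

whole-brain principal gradient
  HC: explained variance g1=0.156, g2=0.152, ...
  HC: gradient-1 range (group mean matrix) 0.2588
  MDD: gradient-1 range (group mean matrix) 0.2567

insula sub-gradients (8 targets; gradient-1 explained variance)
  HC: whole_brain=0.353, VN=0.358, SMN=0.358, DAN=0.356, ...

group tests (pooled-variance t):
  whole_brain_gradient1_range: t(70) = 1.936, p = 0.057
  insula_whole_brain_gradient1_range: t(70) = -18.483, p = 0.000

insula-DAN mean gradient vs HAM-D: MDD r = 0.214 (n=38), HC r = 0.202 (n=34)
```

Reading this: the first whole-brain gradient explains ~16% of connectome
variance in each group and orders parcels along the planted
unimodal→transmodal axis. The cohort was generated with the default
insular profile-convergence effect in the patient group, and the
insula-to-whole-brain gradient-1 range is correspondingly smaller in MDD
(highly significant at the planted effect size, t(70) = −18.5), while
whole-brain range and explained variance do not differ. The run
directory also contains the parcel-wise ANCOVA table, both mixed-ANOVA
tables, endpoint-subdivision and anterior–posterior separation summaries,
per-subject alignment QC, and the resolved configuration.

The library surface mirrors the pipeline: `compute_fc`,
`compute_gradients`, `run_insula_pipeline`, `parcelwise_ancova`,
`mixed_anova`, `fisher_rz_compare`, `simulate_cohort`, … — see the module
docstrings under `src/gradsuite/`.

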