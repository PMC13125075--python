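# Methods

## The model

A functional gradient is an eigenvector of a diffusion operator built on
the similarity graph of regional connectivity profiles. Given a
parcel-level Fisher-z connectivity matrix, the pipeline is:

1. **Profile sparsification.** Each region's connectivity profile (matrix
   row) retains its strongest 10% of entries *by signed value* (ties
   toward the lower index; `ceil` guarantees at least one survivor).
   Signed rather than absolute retention drops strong negative
   correlations, the convention of the reference gradient toolboxes.
   Retention is per profile, so every region keeps the same number of
   connections and no profile can be emptied by competition inside a
   target's column. (`sparsify_columns` itself is a column-wise operator;
   the pipeline feeds it the transpose.)
2. **Normalized-angle affinity.** For rows x, y:
   `a(x, y) = 1 − arccos(cos(x, y))/π ∈ [0, 1]`. It is scale invariant per
   profile and maps anticorrelated profiles to 0, orthogonal to ½,
   identical to 1.
3. **Diffusion-map embedding.** With affinity A and degrees d,
   `W = A/(d_i^α d_j^α)` (α = 0.5 removes sampling-density effects), the
   row-stochastic `P = D̃⁻¹W` is eigendecomposed through its symmetric
   conjugate `S = D̃^{-1/2} W D̃^{-1/2}` (dense `eigh`; deterministic).
   Right eigenvectors are normalized by the trivial stationary
   eigenvector — a scalar for connected graphs, which also keeps the
   computation finite when a degenerate (near-disconnected) input makes
   the eigenvalue-1 eigenspace multi-dimensional. The constant
   eigenvector is dropped; component i is `ψ_i · λ_i/(1−λ_i)`
   (diffusion time 0; `λ^t` for t > 0). Eigenvalues are clipped to
   `[0, 1−10⁻¹²]`: small negative values are numerical noise and a second
   unit eigenvalue signals disconnection, where the multi-scale weight
   would diverge.
4. **Alignment.** Orthogonal Procrustes rotation (no centering/scaling)
   onto the healthy-control template, then a per-column sign flip
   enforcing non-negative correlation with the template component. The
   unaligned template fixes signs by a non-negative first loading.
   Explained-variance ratios are the retained eigenvalues scaled to sum
   to one.

Defaults: 10 components for the 400-parcel whole-brain embedding, 3 for
the 17-parcel insula embeddings; sparsity 0.10; α = 0.5; diffusion time 0.
An all-equal affinity returns zero scores with a `degenerate` flag rather
than an error, so synthetic edge cases cannot crash a cohort run.

## Insula sub-gradients

Eight submatrices per connectivity matrix — insula×whole-brain (17×400)
and insula×network (17×D, D ∈ {61, 77, 46, 47, 26, 52, 91}) — each run
through the same pipeline, giving eight 17×17 affinities and gradient
sets, aligned target-wise to the healthy-control bundle. Readouts:

* **Endpoint subdivisions**: the anatomical tags (vAI, dAI,
  dAI-frontal-operculum, posterior) of the argmin/argmax parcels of
  gradient 1; ties resolve to the lowest parcel id with a logged warning.
* **Anterior–posterior separation**:
  `d = |mean(anterior) − mean(posterior)| / pooled SD` over the insula
  gradient scores (anterior = vAI + dAI + dAI-frontal-operculum), with
  LH-/RH-restricted variants. A zero pooled SD is reported as `d = ∞`
  (separated constants) or `d = 0` (identical constants) with a
  degeneracy flag. This statistic is this package's explicit
  quantification of a judgement that is often made by visual inspection
  of surface maps; it has no canonical literature form.

## Group inference

* **Parcel-wise ANCOVA**: `score ~ group + age + gender` per parcel
  (vectorized OLS; verified to machine precision against statsmodels),
  F for the group effect, Benjamini–Hochberg step-up FDR across all
  parcels. Effect size is partial η²; the group coefficient is the
  adjusted MDD−HC mean difference with its 95% CI.
* **Mixed-design ANOVA** (2-group × within factors, covariates age and
  gender): classical multi-stratum split-plot GLM. The between stratum is
  an ANCOVA on subject means. Each within stratum regresses
  subject-demeaned cell means on sum-coded factor, group×factor and
  covariate×factor terms (Type III drop-term F; error = subject×factor
  stratum with df `(levels−1)(N − groups − covariates)`). On
  covariate-free balanced designs this reproduces `pingouin.mixed_anova`
  exactly (tested); under unbalanced groups the within main effects are
  Type III, the SPSS convention. Greenhouse–Geisser ε from the pooled
  within-group cell covariance is reported alongside each within-stratum
  p but does not replace the headline p. Per-cell group contrasts are
  covariate-adjusted ANCOVAs with Bonferroni correction; the family size
  defaults to the number of cells (17 or 7×17) and is configurable.
* **Gradient-range / explained-variance comparisons**: two-sample
  pooled-variance t (df = n₁+n₂−2).
* **Symptom correlations**: Pearson r of the per-subject mean insula
  gradient (per target) with HAM-D, within group; groups compared by
  Fisher's r-to-z, `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3))`.
  Two-sided p is the default; a one-sided option exists because published
  worked examples of this comparison sometimes print the one-tailed p.

## Synthetic cohorts

The generator emulates exactly the statistical structure the analysis
assumes, with ground truth:

* **Latent axis.** Every parcel has a coordinate c on one
  unimodal→transmodal axis. The seven networks tile the axis (archetypes
  VN 0.05 … DMN 0.95, within-network spread ±0.09) so connectivity decays
  smoothly along it; insula parcels span the full axis through an
  anterior–posterior coordinate u ∈ [0, 1] (0 posterior, 1 ventral
  anterior; right-hemisphere coordinates staggered half a step so
  homologues are similar but not identical). Mean connectivity:
  `Z_ij = z0 + b·[same network] + a·K(c_i, c_j)` with Gaussian kernel
  scale ℓ. Defaults (Fisher-z units): z0 = 0.05, b = 0.08, a = 0.45,
  ℓ = 0.25 — chosen so same-network and near-axis connectivity sit in the
  empirically typical z range (~0.1–0.6) and the kernel, not the block
  term, dominates profile ordering.
* **Insula coupling loci.** Each non-insula parcel also carries a locus
  v ∈ [0, 1] spread across its network; insula rows mix the axis kernel
  with a sharper kernel on (u, v) (weight 0.7, scale 0.1). This gives
  each insula parcel a distinctive profile within every network — the
  property that makes insula-to-network gradients identifiable — while
  insula–insula similarity still decays smoothly in u.
* **Group effect δ** ("profile convergence"): each insula profile in the
  patient group is mixed with weight δ toward the profile of the axis
  midpoint, eroding anterior–posterior differentiation; δ = 1 collapses
  the insular gradient entirely. The embedded gradient-1 range shrinks
  monotonically in δ (range ratio ≈ 1.00 / 0.97 / 0.72 at δ = 0 / 0.25 /
  0.5). Default δ = 0.3.
* **Noise.** Subject matrices add symmetric white Gaussian noise with
  entry sd σ = 0.08, a typical inter-subject z dispersion. Diagonals are
  fixed at 0 throughout; noise lives in z space so the mean/noise
  decomposition is exact. An optional stationary "texture" field
  (default off) adds population-level parcel-pair heterogeneity.
* **Covariates and symptoms.** Age ~ N(38, 11.5²) clipped to [18, 75],
  gender Bernoulli(½); HAM-D margins N(26.71, 5.93²) for patients and
  N(1.39, 1.46²) truncated at 0 for controls, rounded to integers. The
  symptom coupling ρ (default 0.35) is planted by a Gaussian copula on
  each subject's *realized* insula–DAN mean gradient, computed with the
  same template construction (sample control average) the analysis later
  uses — so recovery tests measure the pipeline, not a proxy.
* **Pure-axis connectome** (`simulate_axis_connectome`): the kernel alone
  on `c = linspace(0, 1, P)`, used to verify 1-D manifold recovery
  (Spearman ≥ 0.99 noiseless, ≥ 0.95 at default noise).

What the generator does **not** model: cortical geometry and parcel
adjacency, hemodynamics, head motion, scanner noise spectra, negative
z baselines, site/batch structure. Passing recovery tests therefore
demonstrates correctness of the pipeline's mathematics and inference
calibration under the planted model — not performance on real scans,
where profile structure is richer and motion artifacts matter.

## Numerical and design choices

* Fisher transform clips |r| at 1−10⁻⁷; self-connectivity is fixed at 0
  in z space so it cannot dominate sparsification.
* Confound derivatives are backward differences with a zero first row;
  quadratic terms are elementwise squares of the 12 motion/derivative
  columns; the first volume's missing FD/DVARS count as 0 for flagging.
* Motion-flagged volumes are reported, not removed; `--scrub` enables
  dropping them. All-flagged inputs are a degenerate-input error.
* Alignment QC excludes subjects whose aligned principal gradient
  correlates with the template below 0.4 (configurable); exclusions are
  logged and propagate to all downstream n.
* The dense symmetric eigensolver makes every stage deterministic; the
  config seed is recorded for provenance and feeds only the synthetic
  generator.
* Test and acceptance problem sizes: oracle checks at N ≤ 20;
  cohort-level recovery statements use 100 simulated cohorts at the
  default 38/34 subjects and 400 parcels (reduced rep counts, fixed
  seeds, inside the regular test suite); the end-to-end runner tests use
  an 80-parcel / 8-insula reduction of the same structure.

## Known limitations

* The mixed ANOVA requires complete within-subject cells; unbalanced
  within structure is rejected, not imputed.
* Greenhouse–Geisser correction uses the pooled covariance across both
  groups; tiny groups make ε unstable.
* The insula subdivision lookup ships with only the six published parcel
  assignments for real atlas labels; the remaining parcels must be
  supplied by the user (the synthetic parcellation tags all of its
  parcels from ground truth).
* The separation statistic presumes at least one anterior and one
  posterior parcel per (hemisphere-restricted) subset.
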