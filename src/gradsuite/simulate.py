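"""Synthetic cohorts with planted gradient structure.

The generator emulates the statistical structure the gradient analysis
assumes, with full ground truth:

* a 400-parcel, 7-network parcellation with Schaefer-style labels and 17
  insula parcels inside the salience network;
* every parcel carries a latent coordinate on a single unimodal→transmodal
  axis: non-insula parcels sit near their network's archetype position,
  insula parcels span the full axis along an anterior–posterior coordinate
  ``u`` ∈ [0, 1] (0 = posterior, 1 = ventral anterior);
* the population-mean Fisher-z connectivity is a smooth kernel on that
  axis plus a same-network block boost:
  ``Z_ij = z0 + b·[net_i = net_j] + a·exp(−(c_i − c_j)²/ℓ²)``;
* every non-insula parcel additionally carries an "insula-coupling locus"
  ``v`` spread over the full axis within its network, and insula rows mix
  the axis kernel with a kernel on (u_i − v_j); this emulates the fact
  that each network contains parcels preferentially coupled to different
  insular levels, and gives every insula parcel a distinctive
  connectivity fingerprint within every network;
* the patient-like (MDD) group's insula profiles are differentiated less:
  each insula parcel's connectivity profile is mixed with weight δ toward
  the profile of the axis midpoint, so anterior and posterior insula
  converge on a common connectivity pattern (δ = 1 erases the axis
  entirely and the insular gradient collapses); subject matrices add
  symmetric Gaussian noise in z space;
* HAM-D symptom scores are coupled to each subject's realized insula–DAN
  mean gradient through a Gaussian copula, so the target correlation ρ is
  planted within group on the exact quantity the analysis later estimates.

What it deliberately does not model: cortical geometry, hemodynamics,
head motion, or scanner noise spectra.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ContractError
from .gradients import EmbeddingConfig, INSULA_COMPONENTS, compute_gradients
from .insula import extract_submatrix
from .parcellation import NETWORKS, ParcellationScheme

DEFAULT_NETWORK_SIZES = {"VN": 61, "SMN": 77, "DAN": 46, "SN": 47,
                         "LN": 26, "CN": 52, "DMN": 91}

#: archetype positions of the seven networks on the latent axis
NETWORK_ARCHETYPES = {"VN": 0.05, "SMN": 0.20, "DAN": 0.35, "SN": 0.50,
                      "LN": 0.62, "CN": 0.78, "DMN": 0.95}

SCHAEFER_TOKEN = {"VN": "Vis", "SMN": "SomMot", "DAN": "DorsAttn",
                  "SN": "SalVentAttn", "LN": "Limbic", "CN": "Cont",
                  "DMN": "Default"}


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the study-like conditions.

    Connectome structure: ``baseline`` (z0), ``block_strength`` (b),
    ``axis_strength`` (a) and ``kernel_scale`` (ℓ) set the mean Fisher-z
    matrix; ``noise_sd`` (σ) is the per-subject symmetric z-noise.
    ``group_effect`` (δ) compresses the MDD insula axis; ``symptom_coupling``
    (ρ) is the within-group HAM-D ↔ insula–DAN gradient correlation.
    """

    n_parcels: int = 400
    network_sizes: dict = field(default_factory=lambda: dict(DEFAULT_NETWORK_SIZES))
    n_insula: int = 17
    n_mdd: int = 38
    n_hc: int = 34
    kernel_scale: float = 0.25
    block_strength: float = 0.08
    axis_strength: float = 0.45
    baseline: float = 0.05
    noise_sd: float = 0.08
    group_effect: float = 0.3
    symptom_coupling: float = 0.35
    within_network_jitter: float = 0.09
    insula_target_mix: float = 0.7   # weight of the coupling-locus kernel in insula rows
    locus_scale: float = 0.1         # width of the coupling-locus kernel
    texture_sd: float = 0.0          # optional population-level parcel-pair fingerprint sd
    age_mean: float = 38.0
    age_sd: float = 11.5
    hamd_mdd: tuple[float, float] = (26.71, 5.93)
    hamd_hc: tuple[float, float] = (1.39, 1.46)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.network_sizes.values()) != self.n_parcels:
            raise ContractError("network sizes must sum to n_parcels")
        if self.n_insula > self.network_sizes["SN"]:
            raise ContractError("n_insula cannot exceed the SN size")
        if self.n_mdd < 2 or self.n_hc < 2:
            raise ContractError("need at least 2 subjects per group")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-deriving it."""

    latent_coords: np.ndarray        # per-parcel axis coordinate
    insula_u: np.ndarray             # anterior–posterior coordinate, 17 parcels
    insula_indices: np.ndarray       # 0-based parcel indices of the insula
    group_effect: float              # planted insula profile-convergence δ (MDD)
    symptom_coupling: float
    subject_groups: np.ndarray
    subject_insula_dan_gradient: np.ndarray  # realized coupling variable


def _insula_u(n_lh: int, n_rh: int) -> np.ndarray:
    """Anterior–posterior coordinates covering [0, 1] in both hemispheres.

    The right-hemisphere coordinates are staggered half a step relative to
    the left so no two parcels coincide exactly (homologous parcels are
    similar, not identical, in real data) and the pooled set tiles the
    axis evenly.
    """
    lh = np.linspace(0, 1, n_lh)
    rh = (np.arange(n_rh) + 0.5) / n_rh
    return np.concatenate([lh, rh])


def _subdivision_for_u(u: float) -> str:
    if u < 1 / 3:
        return "posterior"
    if u < 2 / 3:
        return "dAI"
    return "vAI"


def latent_structure(spec: CohortSpec,
                     ) -> tuple[ParcellationScheme, np.ndarray, np.ndarray]:
    """Build the synthetic parcellation together with its latent geometry.

    Parcels are laid out network block by network block (insula parcels
    contiguous at the end of the SN block, split 9 LH / 8 RH at the default
    size). Returns (scheme, axis coordinates c, coupling loci v); insula
    subdivisions are tagged from the anterior–posterior coordinate
    (u < 1/3 posterior, 1/3 ≤ u < 2/3 dAI, u ≥ 2/3 vAI), and insula
    parcels have c = v = u.
    """
    rows, coords, loci = [], [], []
    n_lh_ins = (spec.n_insula + 1) // 2
    n_rh_ins = spec.n_insula - n_lh_ins
    u_ins = _insula_u(n_lh_ins, n_rh_ins)
    for net in NETWORKS:
        size = spec.network_sizes[net]
        n_plain = size - (spec.n_insula if net == "SN" else 0)
        jitter = (np.linspace(-1, 1, n_plain) * spec.within_network_jitter
                  if n_plain > 1 else np.zeros(n_plain))
        v_net = np.linspace(0, 1, n_plain) if n_plain > 1 else np.full(n_plain, 0.5)
        for i in range(n_plain):
            hemi = "LH" if i < (n_plain + 1) // 2 else "RH"
            k = i + 1 if hemi == "LH" else i - (n_plain + 1) // 2 + 1
            rows.append({"label": f"7Networks_{hemi}_{SCHAEFER_TOKEN[net]}_Syn_{k}",
                         "hemisphere": hemi, "network": net,
                         "insula_subdivision": "unassigned"})
            coords.append(NETWORK_ARCHETYPES[net] + jitter[i])
            loci.append(v_net[i])
        if net == "SN":
            for j, u in enumerate(u_ins):
                hemi = "LH" if j < n_lh_ins else "RH"
                k = j + 1 if hemi == "LH" else j - n_lh_ins + 1
                rows.append({"label": f"7Networks_{hemi}_SalVentAttn_FrOperIns_{k}",
                             "hemisphere": hemi, "network": "SN",
                             "insula_subdivision": _subdivision_for_u(u)})
                coords.append(u)
                loci.append(u)
    table = pd.DataFrame(rows)
    table.insert(0, "parcel_id", np.arange(1, len(table) + 1))
    return ParcellationScheme(table), np.asarray(coords), np.asarray(loci)


def make_parcellation(spec: CohortSpec) -> ParcellationScheme:
    """The synthetic Schaefer-style parcellation (see latent_structure)."""
    return latent_structure(spec)[0]


def mean_matrix(spec: CohortSpec, coords: np.ndarray, loci: np.ndarray,
                networks: np.ndarray, insula_mask: np.ndarray,
                insula_convergence: float = 0.0) -> np.ndarray:
    """Population-mean Fisher-z matrix for one set of latent coordinates.

    Non-insula pairs use the axis kernel on c; pairs involving an insula
    parcel mix the axis kernel with the coupling-locus kernel on (u, v),
    which reduces to the pure axis kernel for insula–insula pairs (where
    c = v = u).

    ``insula_convergence`` (δ) plants the group effect: each insula
    parcel's smooth profile is mixed with weight δ toward the profile of
    the axis midpoint, so anterior and posterior insula lose their
    differentiation; at δ = 1 all insula profiles coincide and the insular
    gradient collapses.
    """
    ell = spec.kernel_scale
    K = np.exp(-((coords[:, None] - coords[None, :]) / ell) ** 2)
    w = spec.insula_target_mix
    ins = np.flatnonzero(insula_mask)
    u = coords[ins]
    loci = loci.copy()
    loci[ins] = u
    K_ins = ((1 - w) * np.exp(-((u[:, None] - coords[None, :]) / ell) ** 2)
             + w * np.exp(-((u[:, None] - loci[None, :]) / spec.locus_scale) ** 2))
    if insula_convergence > 0:
        u0 = u.mean()
        K_common = ((1 - w) * np.exp(-((u0 - coords[None, :]) / ell) ** 2)
                    + w * np.exp(-((u0 - loci[None, :]) / spec.locus_scale) ** 2))
        K_ins = (1 - insula_convergence) * K_ins + insula_convergence * K_common
    K[ins, :] = K_ins
    K[:, ins] = K_ins.T
    same = networks[:, None] == networks[None, :]
    Z = spec.baseline + spec.block_strength * same + spec.axis_strength * K
    Z = (Z + Z.T) / 2.0
    np.fill_diagonal(Z, 0.0)
    return Z


def _truncated_normal(mean: float, sd: float, low: float,
                      q: np.ndarray) -> np.ndarray:
    a = (low - mean) / sd
    return sps.truncnorm.ppf(q, a, np.inf, loc=mean, scale=sd)


def _symmetric_noise(shape: tuple, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Symmetric Gaussian field with entry standard deviation sd, zero diag."""
    E = rng.standard_normal(shape)
    N = (E + E.T) / np.sqrt(2.0) * sd
    np.fill_diagonal(N, 0.0)
    return N


def simulate_cohort(spec: CohortSpec,
                    ) -> tuple[list[np.ndarray], pd.DataFrame, GroundTruth]:
    """Draw a full synthetic cohort.

    Returns (subject z-matrices in cohort order, subject table with
    group/age/gender/HAM-D, ground truth). Identical spec + seed yields a
    bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    scheme, coords_hc, loci = latent_structure(spec)
    networks = scheme.networks.to_numpy()
    ins = scheme.insula_indices()
    ins_mask = scheme.insula_mask()
    u = coords_hc[ins].copy()

    Z_hc = mean_matrix(spec, coords_hc, loci, networks, ins_mask)
    Z_mdd = mean_matrix(spec, coords_hc, loci, networks, ins_mask,
                        insula_convergence=spec.group_effect)
    if spec.texture_sd > 0:
        # population-level structural texture: stable parcel-pair
        # fingerprints shared by both groups and all subjects
        texture = _symmetric_noise(Z_hc.shape, spec.texture_sd, rng)
        Z_hc = Z_hc + texture
        Z_mdd = Z_mdd + texture

    n = spec.n_mdd + spec.n_hc
    groups = np.array(["MDD"] * spec.n_mdd + ["HC"] * spec.n_hc)
    matrices: list[np.ndarray] = []
    for g in groups:
        base = Z_mdd if g == "MDD" else Z_hc
        if spec.noise_sd > 0:
            M = base + _symmetric_noise(base.shape, spec.noise_sd, rng)
        else:
            M = base.copy()
        np.fill_diagonal(M, 0.0)
        matrices.append(M)

    # realized insula–DAN mean gradient per subject (the coupling variable),
    # aligned to the template built from the sample HC average — the same
    # template construction the analysis uses, so the planted correlation
    # lives on exactly the quantity the pipeline later measures
    cfg = EmbeddingConfig(n_components=min(INSULA_COMPONENTS, len(ins) - 1))
    hc_sample_mean = np.mean([m for m, g in zip(matrices, groups)
                              if g == "HC"], axis=0)
    np.fill_diagonal(hc_sample_mean, 0.0)
    tmpl = compute_gradients(extract_submatrix(hc_sample_mean, scheme, "DAN"),
                             cfg)
    dan_mean = np.empty(n)
    for i, M in enumerate(matrices):
        gs = compute_gradients(extract_submatrix(M, scheme, "DAN"), cfg,
                               template=tmpl, template_id="HC:DAN")
        dan_mean[i] = gs.scores[:, 0].mean()

    # covariates and copula-coupled HAM-D
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18, 75)
    gender = rng.choice(["F", "M"], size=n)
    hamd = np.zeros(n)
    rho = spec.symptom_coupling
    for g, (mu, sd), low in (("MDD", spec.hamd_mdd, 0.0),
                             ("HC", spec.hamd_hc, 0.0)):
        sel = np.flatnonzero(groups == g)
        zg = sps.norm.ppf((sps.rankdata(dan_mean[sel]) - 0.5) / sel.size)
        zh = rho * zg + np.sqrt(max(1 - rho ** 2, 0.0)) * rng.standard_normal(sel.size)
        q = np.clip(sps.norm.cdf(zh), 1e-9, 1 - 1e-9)
        hamd[sel] = np.round(_truncated_normal(mu, sd, low, q))

    cohort = pd.DataFrame({
        "subject_id": [f"sub-{g.lower()}{i + 1:02d}"
                       for i, g in enumerate(groups)],
        "group": groups, "age": np.round(age, 1), "gender": gender,
        "hamd": hamd.astype(int),
    })
    truth = GroundTruth(coords_hc, u, ins, spec.group_effect,
                        rho, groups, dan_mean)
    return matrices, cohort, truth


def simulate_axis_connectome(n_parcels: int = 400, noise_sd: float = 0.0,
                             kernel_scale: float = 0.25,
                             axis_strength: float = 0.45,
                             baseline: float = 0.05,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A connectome generated purely from a 1-D latent axis.

    Parcels sit at ``c = linspace(0, 1, P)`` and connectivity is the smooth
    axis kernel alone (no network blocks, no insula mixture):
    ``Z_ij = z0 + a·exp(−(c_i − c_j)²/ℓ²)`` plus optional symmetric noise.
    Used to verify that the embedding recovers a planted 1-D manifold.
    Returns (z-matrix, latent coordinates).
    """
    c = np.linspace(0.0, 1.0, n_parcels)
    Z = baseline + axis_strength * np.exp(
        -((c[:, None] - c[None, :]) / kernel_scale) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        E = rng.standard_normal(Z.shape)
        Z = Z + (E + E.T) / np.sqrt(2.0) * noise_sd
    np.fill_diagonal(Z, 0.0)
    return Z, c


def simulate_timeseries(fc_target: np.ndarray, T: int, seed: int = 0,
                        ) -> np.ndarray:
    """Sample a T×P series whose population correlation matches a z-matrix.

    The z-target is mapped back to correlations (tanh), repaired to the
    nearest valid correlation matrix by eigenvalue clipping, and sampled as
    correlated Gaussians; ``compute_fc`` on the output converges to the
    repaired target as T grows.
    """
    Z = np.asarray(fc_target, dtype=float)
    R = np.tanh(Z)
    np.fill_diagonal(R, 1.0)
    evals, evecs = np.linalg.eigh((R + R.T) / 2.0)
    evals = np.clip(evals, 1e-8, None)
    R = (evecs * evals) @ evecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)  # renormalize to unit diagonal
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    rng = np.random.default_rng(seed)
    return rng.standard_normal((T, len(R))) @ L.T
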