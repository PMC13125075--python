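"""Gradient mathematics: sparsification, normalized-angle affinity,
diffusion-map embedding vs a dense oracle, Procrustes alignment, and the
scalar gradient summaries."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import eig

from gradsuite import (EmbeddingConfig, compute_gradients,
                       diffusion_map_embedding, endpoint_parcels,
                       explained_variance, gradient_range,
                       network_mean_scores, normalized_angle_affinity,
                       procrustes_align, sparsify_columns)
from gradsuite.exceptions import ContractError, DegenerateDataError
from gradsuite.gradients import GradientSet

from conftest import random_affinity


# ---------------------------------------------------------------------------
# sparsification

def test_sparsify_column_keeps_largest_signed():
    col = np.arange(1.0, 11.0)[:, None]
    out = sparsify_columns(col, 0.10)
    expected = np.zeros((10, 1))
    expected[9, 0] = 10.0
    np.testing.assert_array_equal(out, expected)


def test_sparsify_retain_one_is_identity(rng):
    M = rng.normal(size=(6, 6))
    np.testing.assert_array_equal(sparsify_columns(M, 1.0), M)


def test_sparsify_400_matrix_keeps_40_per_column(rng):
    M = rng.normal(size=(400, 400))
    out = sparsify_columns(M, 0.10)
    assert ((out != 0).sum(axis=0) == 40).all()


def test_sparsify_signed_not_magnitude():
    """Strong negative entries are dropped, not kept."""
    col = np.array([[-100.0], [1.0], [2.0], [3.0]])
    out = sparsify_columns(col, 0.25)
    assert out[0, 0] == 0.0 and out[3, 0] == 3.0


def test_sparsify_tie_breaks_to_lowest_row_index():
    col = np.array([[5.0], [5.0], [5.0], [0.0]])
    out = sparsify_columns(col, 0.25)  # ceil(0.25*4) = 1 kept
    assert out[0, 0] == 5.0 and (out[1:] == 0).all()


def test_sparsify_ceil_keeps_two_of_seventeen(rng):
    M = rng.normal(size=(17, 5))
    out = sparsify_columns(M, 0.10)
    assert ((out != 0).sum(axis=0) == 2).all()
    with pytest.raises(ContractError):
        sparsify_columns(M, 0.0)


# ---------------------------------------------------------------------------
# affinity

def test_affinity_reference_angles():
    M = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0], [-3.0, 0.0]])
    A = normalized_angle_affinity(M)
    assert A[0, 1] == pytest.approx(1.0)     # identical direction
    assert A[0, 2] == pytest.approx(0.5)     # orthogonal
    assert A[0, 3] == pytest.approx(0.0)     # antiparallel


def test_affinity_bounds_symmetry_diagonal(rng):
    for _ in range(50):
        n = rng.integers(4, 20)
        A = normalized_angle_affinity(rng.normal(size=(n, n + 5)))
        assert A.shape == (n, n)
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert A.min() >= 0.0 and A.max() <= 1.0
        np.testing.assert_allclose(np.diag(A), 1.0)


def test_affinity_zero_row_names_row(rng):
    M = rng.normal(size=(5, 8))
    M[3] = 0.0
    with pytest.raises(DegenerateDataError, match=r"\[3\]"):
        normalized_angle_affinity(M)


# ---------------------------------------------------------------------------
# diffusion-map embedding

def dense_diffusion_oracle(A: np.ndarray, k: int, alpha: float = 0.5):
    """Independent route: explicitly build the anisotropic transition
    matrix, run a dense nonsymmetric eigendecomposition, and normalize the
    eigenvectors through the symmetric-conjugate (unit-norm) convention.
    """
    d = A.sum(axis=1)
    W = A / np.outer(d ** alpha, d ** alpha)
    d2 = W.sum(axis=1)
    P = W / d2[:, None]
    evals, evecs = eig(P)
    order = np.argsort(-evals.real)
    evals, evecs = evals.real[order], evecs.real[:, order]
    # rescale each right eigenvector so its symmetric-conjugate image
    # sqrt(d2)*v has unit norm, then divide by the trivial eigenvector
    U = evecs * np.sqrt(d2)[:, None]
    evecs = evecs / np.linalg.norm(U, axis=0)
    psi = evecs / evecs[:, [0]]
    lam = evals[1:k + 1]
    return psi[:, 1:k + 1] * (lam / (1 - lam)), lam


def test_embedding_matches_dense_oracle(rng):
    """20 random affinities (N ≤ 20): scores and eigenvalues match the
    dense oracle to 1e-8 up to per-column sign."""
    worst = 0.0
    for _ in range(20):
        n = int(rng.integers(5, 21))
        A = random_affinity(rng, n)
        k = min(4, n - 2)
        gs = diffusion_map_embedding(A, EmbeddingConfig(n_components=k))
        scores_o, lam_o = dense_diffusion_oracle(A, k)
        for j in range(k):
            if scores_o[:, j] @ gs.scores[:, j] < 0:
                scores_o[:, j] = -scores_o[:, j]
        worst = max(worst, np.abs(scores_o - gs.scores).max(),
                    np.abs(lam_o - gs.eigenvalues).max())
    assert worst < 1e-8


def test_embedding_all_equal_affinity_degenerate():
    A = np.ones((6, 6))
    gs = diffusion_map_embedding(A, EmbeddingConfig(n_components=2))
    assert gs.degenerate
    np.testing.assert_array_equal(gs.scores, 0.0)


def test_embedding_block_diagonal_sign_separates_blocks():
    A = np.zeros((6, 6))
    A[:3, :3] = 1.0
    A[3:, 3:] = 1.0
    gs = diffusion_map_embedding(A, EmbeddingConfig(n_components=1))
    signs = np.sign(gs.scores[:, 0])
    assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
    assert signs[0] != signs[3]


def test_embedding_invariants(rng):
    for _ in range(10):
        A = random_affinity(rng, int(rng.integers(8, 16)))
        gs = diffusion_map_embedding(A, EmbeddingConfig(n_components=4))
        assert (np.diff(gs.eigenvalues) <= 1e-12).all()
        assert gs.explained_variance.sum() == pytest.approx(1.0)
        assert (gs.scores.std(axis=0) > 0).all()


def test_embedding_contract_errors(rng):
    A = random_affinity(rng, 6)
    with pytest.raises(ContractError):
        diffusion_map_embedding(A, EmbeddingConfig(n_components=6))
    bad = A.copy()
    bad[0, 1] = bad[1, 0] + 0.5
    with pytest.raises(ContractError):
        diffusion_map_embedding(bad, EmbeddingConfig(n_components=2))
    neg = A - 2.0
    with pytest.raises(ContractError):
        diffusion_map_embedding(neg, EmbeddingConfig(n_components=2))


# ---------------------------------------------------------------------------
# Procrustes alignment

def _gradset(scores):
    k = scores.shape[1]
    lam = np.linspace(0.5, 0.3, k)
    return GradientSet(scores, lam, lam / lam.sum())


def test_procrustes_identity(rng):
    t = _gradset(rng.normal(size=(17, 3)))
    aligned = procrustes_align(t, t)
    np.testing.assert_allclose(aligned.scores, t.scores, atol=1e-10)


def test_procrustes_recovers_orthogonal_rotation(rng):
    t = _gradset(rng.normal(size=(17, 3)))
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    src = _gradset(t.scores @ Q)
    aligned = procrustes_align(src, t)
    np.testing.assert_allclose(aligned.scores, t.scores, atol=1e-8)


def test_procrustes_beats_random_rotations(rng):
    """Random-search lower bound: no random orthogonal R does better."""
    src = _gradset(rng.normal(size=(17, 3)))
    t = _gradset(rng.normal(size=(17, 3)))
    aligned = procrustes_align(src, t)
    best = np.linalg.norm(aligned.scores - t.scores)
    for _ in range(1000):
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert np.linalg.norm(src.scores @ Q - t.scores) >= best - 1e-10


def test_procrustes_preserves_frobenius_norm_and_sign_convention(rng):
    src = _gradset(rng.normal(size=(20, 3)))
    t = _gradset(rng.normal(size=(20, 3)))
    aligned = procrustes_align(src, t)
    assert np.linalg.norm(aligned.scores) == pytest.approx(
        np.linalg.norm(src.scores), abs=1e-10)
    for j in range(3):
        assert np.corrcoef(aligned.scores[:, j], t.scores[:, j])[0, 1] >= 0
    with pytest.raises(ContractError):
        procrustes_align(_gradset(rng.normal(size=(5, 2))), t)


# ---------------------------------------------------------------------------
# summaries

def test_explained_variance():
    np.testing.assert_allclose(explained_variance(np.array([2.0, 1.0, 1.0])),
                               [0.5, 0.25, 0.25])
    np.testing.assert_allclose(explained_variance(np.array([5.0])), [1.0])
    v = np.random.default_rng(1).uniform(0.1, 2, 6)
    np.testing.assert_allclose(explained_variance(v), v / v.sum())
    with pytest.raises(DegenerateDataError):
        explained_variance(np.zeros(3))
    with pytest.raises(ContractError):
        explained_variance(np.array([-1.0, 2.0]))


def test_gradient_range():
    """Range = max − min; the published compressed whole-brain endpoints
    −0.1240 / 0.0842 give 0.2082."""
    assert gradient_range(np.array([-0.1240, 0.02, 0.0842])) == pytest.approx(0.2082)
    assert gradient_range(np.full(5, 1.3)) == 0.0
    assert gradient_range(np.array([-1.0, 0.0, 3.0])) == 4.0
    with pytest.raises(ContractError):
        gradient_range(np.array([1.0]))


def test_endpoint_parcels_and_tie_rule(default_scheme):
    ins = default_scheme.insula_indices()[:3]
    scores = np.array([0.1, -0.2, 0.3])
    lo, hi = endpoint_parcels(scores, default_scheme, parcel_indices=ins)
    assert lo["score"] == -0.2 and hi["score"] == 0.3
    assert lo["parcel_id"] == int(default_scheme.table.iloc[ins[1]]["parcel_id"])
    # all-equal scores: both endpoints resolve to the first parcel
    lo, hi = endpoint_parcels(np.zeros(3), default_scheme, parcel_indices=ins)
    assert lo["parcel_id"] == hi["parcel_id"] == int(
        default_scheme.table.iloc[ins[0]]["parcel_id"])


def test_network_mean_scores(default_scheme, rng):
    ones = np.ones(default_scheme.n_parcels)
    tab = network_mean_scores(ones, default_scheme)
    assert (tab["mean"] == 1.0).all() and (tab["sem"] == 0.0).all()

    scores = np.zeros(default_scheme.n_parcels)
    scores[default_scheme.network_indices("DMN")] = 2.0
    tab = network_mean_scores(scores, default_scheme)
    assert tab.set_index("network").loc["DMN", "mean"] == 2.0
    assert tab.set_index("network").loc["VN", "mean"] == 0.0

    r = rng.normal(size=default_scheme.n_parcels)
    tab = network_mean_scores(r, default_scheme)
    for _, row in tab.iterrows():
        sel = r[default_scheme.network_indices(row["network"])]
        assert row["mean"] == pytest.approx(sel.mean())
        assert row["sem"] == pytest.approx(sel.std(ddof=1) / np.sqrt(sel.size))


# ---------------------------------------------------------------------------
# property tests

@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(min_value=4, max_value=30), st.integers(min_value=0, max_value=10_000),
       st.floats(min_value=0.05, max_value=1.0))
def test_sparsify_nonzero_count_property(n, seed, retain):
    M = np.random.default_rng(seed).normal(size=(n, n))
    out = sparsify_columns(M, retain)
    expected = min(int(np.ceil(retain * n)), n)
    assert ((out != 0).sum(axis=0) <= expected).all()
    assert ((out != 0).sum(axis=0) >= 1).all()


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(min_value=3, max_value=15), st.integers(min_value=0, max_value=10_000))
def test_affinity_range_property(n, seed):
    M = np.random.default_rng(seed).normal(size=(n, n + 2))
    A = normalized_angle_affinity(M)
    assert A.min() >= 0.0 and A.max() <= 1.0 + 1e-12
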