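"""Discriminant extractors against dense brute-force oracles.

The oracle takes the naive route the method definition spells out --
dense matrix exponentials, explicit inverse, non-symmetric
eigendecomposition of B = exp(S_w)^{-1} exp(S_b) -- while the
implementation solves the equivalent symmetric-definite problem.  Both
must span the same discriminant subspace.
"""

import numpy as np
import pytest
import scipy.linalg

from filda import (
    SpectraSet,
    ValidationError,
    fit_filda,
    fit_ilda,
    fit_lda,
    fuzzy_memberships,
    fuzzy_scatter_matrices,
    project,
    scatter_matrices,
)
from filda.fuzzy import FuzzyPartition
from conftest import make_scores


def exp_discriminant_oracle(s_b, s_w, q):
    b = np.linalg.inv(scipy.linalg.expm(s_w)) @ scipy.linalg.expm(s_b)
    vals, vecs = np.linalg.eig(b)
    order = np.argsort(-vals.real, kind="stable")
    return np.real(vecs[:, order[:q]])


def subspace_angle(a, b):
    return float(np.max(scipy.linalg.subspace_angles(a, b)))


# ----------------------------------------------------------------------
# classical LDA
# ----------------------------------------------------------------------

def test_lda_recovers_known_separating_direction():
    rng = np.random.default_rng(12)
    direction = np.array([1.0, 0.0])
    n = 300
    x0 = rng.standard_normal((n, 2)) * [0.3, 3.0]
    x1 = x0.copy() + 4.0 * direction
    scores = SpectraSet(
        wavelengths=np.arange(2.0),
        absorbance=np.vstack([x0, x1]),
        labels=np.repeat([0, 1], n),
    )
    model = fit_lda(scores)
    w = model.W[:, 0] / np.linalg.norm(model.W[:, 0])
    angle = np.degrees(np.arccos(min(1.0, abs(w @ direction))))
    assert angle < 1.0
    assert model.W.shape == (2, 1)  # q = c - 1


def test_lda_beats_random_projections_on_fisher_criterion():
    """For two classes the discriminant maximizes the generalized Rayleigh
    quotient tr(W'S_b W)/tr(W'S_w W) over all rank-1 projections."""
    scores = make_scores(n_per_class=15, c=2, k=4, seed=2)
    model = fit_lda(scores)
    sc = scatter_matrices(scores)

    def fisher(w):
        return np.trace(w.T @ sc.s_b @ w) / np.trace(w.T @ sc.s_w @ w)

    rng = np.random.default_rng(0)
    lda_ratio = fisher(model.W)
    for _ in range(20):
        w = rng.standard_normal(model.W.shape)
        assert lda_ratio > fisher(w)


def test_lda_single_class_rejected():
    scores = make_scores(n_per_class=5, c=3, seed=0).subset(range(5))
    with pytest.raises(ValidationError, match="2 classes"):
        fit_lda(scores)


def test_lda_agrees_with_sklearn_eigen_solver(blobs):
    sklearn_lda = pytest.importorskip(
        "sklearn.discriminant_analysis"
    ).LinearDiscriminantAnalysis
    ours = fit_lda(blobs, class_weighted_sb=True)
    ref = sklearn_lda(solver="eigen").fit(blobs.absorbance, blobs.labels)
    assert subspace_angle(ours.W, ref.scalings_[:, : ours.q]) < 1e-6


# ----------------------------------------------------------------------
# exponential discriminants
# ----------------------------------------------------------------------

def test_ilda_runs_with_zero_within_scatter():
    """Every sample at its class mean: S_w = 0, exp(S_w) = I; the projection
    must equal the leading eigenvectors of exp(S_b) (same as those of S_b)."""
    x = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [2.0, 1.0, 0.0], [2.0, 1.0, 0.0]])
    scores = SpectraSet(
        wavelengths=np.arange(3.0), absorbance=x, labels=np.array([0, 0, 1, 1])
    )
    model = fit_ilda(scores)
    assert np.all(np.isfinite(model.W))
    sc = scatter_matrices(scores)
    _, vecs = np.linalg.eigh(sc.s_b)
    assert subspace_angle(model.W, vecs[:, -1:]) < 1e-10


@pytest.mark.parametrize("seed", range(6))
def test_ilda_matches_dense_brute_force_oracle(seed):
    scores = make_scores(n_per_class=3, c=2, k=3, seed=seed)
    model = fit_ilda(scores)
    sc = scatter_matrices(scores)
    oracle = exp_discriminant_oracle(sc.s_b, sc.s_w, q=1)
    assert subspace_angle(model.W, oracle) <= 1e-7


def test_ilda_five_classes_gives_four_discriminant_vectors():
    scores = make_scores(n_per_class=4, c=5, k=6, seed=3)
    assert fit_ilda(scores).W.shape == (6, 4)


@pytest.mark.parametrize("seed", range(6))
def test_filda_matches_dense_brute_force_oracle(seed):
    # modest scale keeps the exponentiated eigenvalue spread well inside
    # float64 so implementation and oracle are both meaningful to 1e-7
    scores = make_scores(n_per_class=4, c=3, k=3, spread=0.5, sep=1.5, seed=100 + seed)
    part = fuzzy_memberships(scores, eta=4.0)
    model = fit_filda(scores, part)
    fsc = fuzzy_scatter_matrices(scores, part)
    oracle = exp_discriminant_oracle(fsc.s_b, fsc.s_w, q=2)
    assert subspace_angle(model.W, oracle) <= 1e-7


def test_filda_crisp_memberships_match_ilda_on_whitened_toy():
    """With one-hot memberships S_fw == S_w, and S_fb == m*S_b; on a toy with
    isotropic within-class scatter the class-size factor only rescales the
    between eigenvalues, so FiLDA and iLDA span the same direction."""
    mean1 = np.array([3.0, 0.0])
    devs = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    x = np.vstack([devs, mean1 + devs])
    labels = np.repeat([0, 1], 4)
    scores = SpectraSet(wavelengths=np.arange(2.0), absorbance=x, labels=labels)
    u = np.zeros((8, 2))
    u[np.arange(8), labels] = 1.0
    centers = np.vstack([np.zeros(2), mean1])
    part = FuzzyPartition(U=u, centers=centers, eta=4.0, c=2)
    fz = fuzzy_scatter_matrices(scores, part)
    crisp = scatter_matrices(scores)
    np.testing.assert_allclose(fz.s_w, crisp.s_w, atol=1e-12)
    assert subspace_angle(fit_filda(scores, part).W, fit_ilda(scores).W) < 1e-8


def test_exponentiated_scatter_is_positive_definite():
    rng = np.random.default_rng(9)
    for _ in range(20):
        x = rng.standard_normal((10, 4))
        u = rng.dirichlet(np.ones(3), size=10)
        centers = rng.standard_normal((3, 4))
        part = FuzzyPartition(U=u, centers=centers, eta=4.0, c=3)
        scores = SpectraSet(
            wavelengths=np.arange(4.0), absorbance=x, labels=rng.integers(0, 3, 10)
        )
        fz = fuzzy_scatter_matrices(scores, part)
        exp_w = scipy.linalg.expm(fz.s_w)
        assert np.linalg.eigvalsh(exp_w).min() > 0


def test_small_sample_size_lda_needs_pinv_but_exponential_variants_do_not():
    scores = make_scores(n_per_class=2, c=2, k=10, seed=6)  # 4 samples, 10-dim
    with pytest.warns(RuntimeWarning, match="pseudo-inverse"):
        lda = fit_lda(scores)
    assert lda.used_pinv
    ilda = fit_ilda(scores)
    part = fuzzy_memberships(scores, eta=4.0)
    filda = fit_filda(scores, part)
    for model in (ilda, filda):
        assert not model.used_pinv
        assert np.all(np.isfinite(model.W))


def test_overflow_guard_rescales_large_scatter():
    scores = make_scores(n_per_class=30, c=2, k=3, spread=10.0, seed=13)
    model = fit_ilda(scores)
    assert model.rescale_factor < 1.0
    assert np.all(np.isfinite(model.W))


# ----------------------------------------------------------------------
# projection
# ----------------------------------------------------------------------

def test_project_shape_linearity_and_mismatch(blobs):
    model = fit_ilda(blobs)
    out = project(model, blobs)
    assert out.absorbance.shape == (blobs.n_samples, model.q)
    zero = SpectraSet(
        wavelengths=np.arange(float(blobs.n_features)),
        absorbance=np.zeros((1, blobs.n_features)),
        labels=np.array([0]),
    )
    np.testing.assert_array_equal(project(model, zero).absorbance, 0.0)
    bad = SpectraSet(
        wavelengths=np.arange(2.0),
        absorbance=np.zeros((1, 2)),
        labels=np.array([0]),
    )
    with pytest.raises(ValidationError, match="features"):
        project(model, bad)
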