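"""Discriminant feature extractors: LDA, iLDA and FiLDA.

Classical LDA maximises the Fisher criterion by eigendecomposing
S_w^{-1} S_b, which requires the within-class scatter to be nonsingular --
the "small sample size" failure mode when features outnumber samples.

The matrix-exponential variant (iLDA, a form of exponential discriminant
analysis) replaces both scatter matrices by their matrix exponentials and
eigendecomposes B = exp(S_w)^{-1} exp(S_b).  Because the exponential of a
symmetric matrix is always symmetric positive definite, B is well defined
even when S_w is singular, and discriminant information in the null space
of S_w is retained rather than discarded.

FiLDA is the same exponential construction applied to the fuzzy scatter
matrices, so noisy or ambiguous samples (low membership everywhere) are
downweighted before the exponentials are taken.

B itself is generally non-symmetric; its eigenpairs coincide with those of
the symmetric-definite generalized problem exp(S_b) w = t exp(S_w) w,
which is what is solved here (real eigenvalues, stable solver).  The naive
non-symmetric route is kept only as a test oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._linalg import exp_discriminant_eig, fix_signs, top_generalized_eig
from .fuzzy import FuzzyPartition
from .scatter import fuzzy_scatter_matrices, scatter_matrices
from .spectra import SpectraSet, ValidationError, class_means

__all__ = ["DiscriminantModel", "fit_lda", "fit_ilda", "fit_filda", "project"]

logger = logging.getLogger(__name__)

#: largest scatter eigenvalue allowed into expm before common rescaling;
#: exp(300) ~ 2e130 still sits comfortably inside double range
EXPM_EIG_CAP = 300.0


@dataclass
class DiscriminantModel:
    """Projection W (k x q, q = c - 1) with fit metadata."""

    W: np.ndarray
    method: str  # lda | ilda | filda
    eigenvalues: np.ndarray
    class_means_projected: np.ndarray
    q: int
    used_pinv: bool = False
    rescale_factor: float = 1.0


def _finalize(
    w: np.ndarray,
    method: str,
    eigenvalues: np.ndarray,
    scores: SpectraSet,
    used_pinv: bool = False,
    rescale_factor: float = 1.0,
) -> DiscriminantModel:
    if not np.all(np.isfinite(w)):
        raise ValidationError(
            f"{method}: non-finite projection; rescale the input scores"
        )
    # Eigenvector scale is arbitrary in the eigenproblem; fix it so every
    # discriminant vector has unit pooled within-class variance on the
    # training scores.  All three extractors then hand the downstream
    # Euclidean classifier a comparably standardized space.
    _, means_in = class_means(scores.absorbance, scores.labels)
    codes = np.unique(scores.labels)
    code_row = np.searchsorted(codes, scores.labels)
    resid = (scores.absorbance - means_in[code_row]) @ w
    sd = resid.std(axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    w = w / sd
    _, means = class_means(scores.absorbance, scores.labels)
    return DiscriminantModel(
        W=w,
        method=method,
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        class_means_projected=means @ w,
        q=w.shape[1],
        used_pinv=used_pinv,
        rescale_factor=rescale_factor,
    )


def _n_discriminants(scores: SpectraSet) -> int:
    c = scores.n_classes
    if c < 2:
        raise ValidationError(f"discriminant analysis needs >= 2 classes, got {c}")
    return c - 1


def fit_lda(scores: SpectraSet, class_weighted_sb: bool = False) -> DiscriminantModel:
    """Classical Fisher discriminant: top q = c-1 eigenvectors of S_w^{-1} S_b.

    Solved as the generalized symmetric-definite problem S_b w = t S_w w
    when S_w is nonsingular.  If S_w is singular (small-sample-size case)
    the Moore-Penrose pseudo-inverse is used instead, with a warning, and
    the model is flagged ``used_pinv``.
    """
    q = _n_discriminants(scores)
    sc = scatter_matrices(scores, class_weighted_sb=class_weighted_sb)
    eigvals_w = np.linalg.eigvalsh(sc.s_w)
    singular = eigvals_w.min() <= max(1e-10 * max(eigvals_w.max(), 0.0), 1e-300)
    if not singular:
        vals, w = top_generalized_eig(sc.s_b, sc.s_w, q)
        return _finalize(w, "lda", vals, scores)
    warnings.warn(
        "within-class scatter is singular; falling back to the pseudo-inverse",
        RuntimeWarning,
        stacklevel=2,
    )
    m = np.linalg.pinv(sc.s_w) @ sc.s_b
    vals, vecs = np.linalg.eig(m)
    order = np.argsort(-vals.real, kind="stable")[:q]
    w = fix_signs(np.real(vecs[:, order]))
    return _finalize(w, "lda", vals.real[order], scores, used_pinv=True)


def _exp_discriminant(
    s_b: np.ndarray,
    s_w: np.ndarray,
    q: int,
    overflow_guard: bool,
) -> tuple[np.ndarray, np.ndarray, float]:
    factor = 1.0
    if overflow_guard:
        top = max(np.linalg.eigvalsh(s_w).max(), np.linalg.eigvalsh(s_b).max())
        if top > EXPM_EIG_CAP:
            factor = EXPM_EIG_CAP / top
            logger.warning(
                "scatter eigenvalue %.3g exceeds %.0f; rescaling both scatter "
                "matrices by %.3g before exponentiation",
                top, EXPM_EIG_CAP, factor,
            )
            s_b = s_b * factor
            s_w = s_w * factor
    vals, w = exp_discriminant_eig(s_b, s_w, q)
    return vals, w, factor


def fit_ilda(
    scores: SpectraSet,
    class_weighted_sb: bool = False,
    overflow_guard: bool = True,
) -> DiscriminantModel:
    """Exponential discriminant on the crisp scatter matrices.

    Forms B = exp(S_w)^{-1} exp(S_b) (as the equivalent generalized
    symmetric-definite eigenproblem) and keeps the top q = c-1
    eigenvectors.  Works for singular S_w, since exp of any symmetric
    matrix is positive definite.  When the largest scatter eigenvalue
    exceeds ``EXPM_EIG_CAP``, both matrices are rescaled by a common
    factor before exponentiation (disable with ``overflow_guard=False``).
    """
    q = _n_discriminants(scores)
    sc = scatter_matrices(scores, class_weighted_sb=class_weighted_sb)
    vals, w, factor = _exp_discriminant(sc.s_b, sc.s_w, q, overflow_guard)
    return _finalize(w, "ilda", vals, scores, rescale_factor=factor)


def fit_filda(
    scores: SpectraSet,
    part: FuzzyPartition,
    overflow_guard: bool = True,
) -> DiscriminantModel:
    """Exponential discriminant on the fuzzy scatter matrices.

    Identical machinery to :func:`fit_ilda` with the membership-weighted
    S_fb, S_fw in place of the crisp S_b, S_w.
    """
    q = _n_discriminants(scores)
    sc = fuzzy_scatter_matrices(scores, part)
    vals, w, factor = _exp_discriminant(sc.s_b, sc.s_w, q, overflow_guard)
    return _finalize(w, "filda", vals, scores, rescale_factor=factor)


def project(model: DiscriminantModel, scores: SpectraSet) -> SpectraSet:
    """Map score vectors into discriminant-vector (DV) space: scores @ W."""
    if scores.n_features != model.W.shape[0]:
        raise ValidationError(
            f"scores have {scores.n_features} features but W expects {model.W.shape[0]}"
        )
    return SpectraSet(
        wavelengths=np.arange(model.q, dtype=float),
        absorbance=scores.absorbance @ model.W,
        labels=scores.labels.copy(),
        sample_ids=list(scores.sample_ids),
    )
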