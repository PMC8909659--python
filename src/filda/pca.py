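"""Principal component reduction of spectra.

High-resolution NIR spectra are massively collinear; almost all variance
lives in a handful of directions.  Reducing to a few principal components
(seven by default, which on typical fruit spectra carries >99.9% of the
variance) removes redundant wavelengths and noise before discriminant
extraction, and keeps the scatter matrices small and well-scaled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import fix_signs
from .spectra import SpectraSet, ValidationError

__all__ = ["PCAModel", "fit_pca", "transform_pca"]

DEFAULT_N_COMPONENTS = 7


@dataclass
class PCAModel:
    """Fitted principal-component model.

    ``loadings`` is ``d x k`` column-orthonormal; ``eigenvalues`` are the
    top-``k`` eigenvalues of the sample covariance (ddof=1), descending.
    """

    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    k: int

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        if not hasattr(self, "total_variance"):
            self.total_variance = float(self.eigenvalues.sum())


def fit_pca(train: SpectraSet, k: int = DEFAULT_N_COMPONENTS) -> PCAModel:
    """Eigendecomposition of the sample covariance of centered spectra.

    Computed through the thin SVD of the centered data matrix, which is the
    same decomposition without forming the d x d covariance.  Loadings carry
    a deterministic sign (largest-magnitude entry of each column positive).
    """
    n, d = train.absorbance.shape
    if n < 2:
        raise ValidationError(f"PCA needs at least 2 samples, got {n}")
    kmax = min(n - 1, d)
    if not 1 <= k <= kmax:
        raise ValidationError(f"k must be in [1, {kmax}] for n={n}, d={d}; got {k}")
    mean = train.absorbance.mean(axis=0)
    xc = train.absorbance - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    model = PCAModel(
        mean=mean,
        loadings=fix_signs(vt[:k].T),
        eigenvalues=eigvals[:k],
        k=k,
    )
    model.total_variance = float(eigvals.sum())
    return model


def transform_pca(model: PCAModel, s: SpectraSet) -> SpectraSet:
    """Project spectra into score space: ``(X - mean) @ loadings``.

    Labels and sample ids are carried through; the feature axis of the
    returned set is the component index ``0..k-1``.
    """
    if s.n_features != model.mean.size:
        raise ValidationError(
            f"spectra have {s.n_features} points but the PCA model expects {model.mean.size}"
        )
    scores = (s.absorbance - model.mean) @ model.loadings
    return SpectraSet(
        wavelengths=np.arange(model.k, dtype=float),
        absorbance=scores,
        labels=s.labels.copy(),
        sample_ids=list(s.sample_ids),
    )
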