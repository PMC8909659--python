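"""Containers for labelled spectral data.

A :class:`SpectraSet` holds one absorbance row per sample over a common,
strictly increasing wavelength grid, together with integer class labels and
string sample identifiers.  The same container carries data through every
stage of the pipeline; after PCA reduction or discriminant projection the
``wavelengths`` axis holds the (integer-valued) component index instead of
nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectraSet", "ValidationError", "class_means"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _as_float_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D array, got ndim={arr.ndim}")
    return arr


@dataclass
class SpectraSet:
    """Absorbance matrix (n samples x d points) with labels and ids.

    Parameters
    ----------
    wavelengths:
        Strictly increasing feature axis, length ``d`` (nanometres for raw
        spectra, component index after projection).
    absorbance:
        ``n x d`` real matrix, one spectrum per row.
    labels:
        Integer class codes, length ``n``.
    sample_ids:
        Unique-ish string identifiers, length ``n``.  Generated as
        ``s0000, s0001, ...`` when not supplied.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.absorbance = _as_float_matrix(self.absorbance, "absorbance")
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        n, d = self.absorbance.shape
        if self.wavelengths.size != d:
            raise ValidationError(
                f"wavelengths length {self.wavelengths.size} != absorbance width {d}"
            )
        if d > 1 and not np.all(np.diff(self.wavelengths) > 0):
            i = int(np.flatnonzero(np.diff(self.wavelengths) <= 0)[0])
            raise ValidationError(
                "wavelengths must be strictly increasing; first offending pair "
                f"({self.wavelengths[i]:g}, {self.wavelengths[i + 1]:g}) at index {i}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance contains non-finite values")
        if self.labels.size != n:
            raise ValidationError(f"labels length {self.labels.size} != n samples {n}")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be nonnegative integer class codes")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"sample_ids length {len(self.sample_ids)} != n samples {n}"
            )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_features(self) -> int:
        return self.absorbance.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted array of class codes present in the set."""
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return self.classes.size

    # ------------------------------------------------------------------
    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """New set with the same metadata but replaced absorbance matrix."""
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            absorbance=np.asarray(absorbance, dtype=float),
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )

    def subset(self, indices) -> "SpectraSet":
        """New set restricted to the given sample indices (order kept)."""
        idx = np.asarray(indices, dtype=int).ravel()
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            absorbance=self.absorbance[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, SpectraSet):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.absorbance, other.absorbance)
            and np.array_equal(self.labels, other.labels)
            and self.sample_ids == other.sample_ids
        )


def class_means(x: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean rows of ``x``.

    Returns ``(codes, means)`` where ``codes`` are the sorted class codes and
    ``means[j]`` is the mean of the rows with ``labels == codes[j]``.
    """
    codes = np.unique(labels)
    means = np.vstack([x[labels == c].mean(axis=0) for c in codes])
    return codes, means
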