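"""Spectral pretreatment operators.

Five standard chemometric pretreatments, each a pure function from
:class:`~filda.spectra.SpectraSet` to :class:`~filda.spectra.SpectraSet`:

* :func:`snv` -- standard normal variate: per-spectrum centering/scaling,
  removes per-sample multiplicative and additive scatter.
* :func:`msc` -- multiplicative scatter correction: per-spectrum affine
  regression against a reference spectrum, then inversion of the fit.
* :func:`mean_center` -- per-wavelength (column) centering with means
  learned on training data.
* :func:`savgol` -- Savitzky-Golay least-squares polynomial smoothing;
  the same operator serves both "smoothing" (default window 11) and
  "filtering" (window 53), the two window widths used in practice.

Operators with learnable state (the MSC reference, the column means) are
fit on training data only; :class:`FittedPreprocessor` packages that
train/apply split for the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet, ValidationError

__all__ = [
    "PreprocessConfig",
    "FittedPreprocessor",
    "snv",
    "msc",
    "mean_center",
    "savgol",
    "PREPROCESS_METHODS",
]

PREPROCESS_METHODS = ("snv", "msc", "mean_center", "sg_smooth", "sg_filter", "none")

#: default Savitzky-Golay windows: narrow for light smoothing, wide for
#: aggressive noise filtering of slowly varying NIR bands
SG_SMOOTH_WINDOW = 11
SG_FILTER_WINDOW = 53


# ----------------------------------------------------------------------
# stateless / row-wise operators
# ----------------------------------------------------------------------

def snv(s: SpectraSet, ddof: int = 1) -> SpectraSet:
    """Standard normal variate: each row to mean 0, standard deviation 1.

    Uses the sample standard deviation (``ddof=1``) by default, the common
    chemometrics convention; pass ``ddof=0`` for the population form.
    Raises for any constant row, for which the transform is undefined.
    """
    x = s.absorbance
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    bad = np.flatnonzero(sd.ravel() <= 0)
    if bad.size:
        raise ValidationError(
            f"snv undefined for constant spectrum (sample id {s.sample_ids[bad[0]]!r})"
        )
    return s.with_absorbance((x - mu) / sd)


def msc(
    s: SpectraSet,
    reference: Optional[np.ndarray] = None,
    b_tol: float = 1e-12,
) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each row ``x`` is regressed on the reference, ``x ~ a + b*ref`` by
    ordinary least squares, and replaced by ``(x - a) / b``.  The default
    reference is the column mean of ``s`` itself; in a train/test setting
    pass the training-set mean explicitly (see :class:`FittedPreprocessor`).
    """
    x = s.absorbance
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, dtype=float).ravel()
    if ref.size != s.n_features:
        raise ValidationError(
            f"msc reference length {ref.size} != spectrum length {s.n_features}"
        )
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise ValidationError("msc reference has zero spread")
    # closed-form simple regression per row
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    bad = np.flatnonzero(np.abs(b) <= b_tol)
    if bad.size:
        raise ValidationError(
            f"msc fitted slope ~ 0 for sample id {s.sample_ids[bad[0]]!r}"
        )
    a = x.mean(axis=1) - b * ref.mean()
    return s.with_absorbance((x - a[:, None]) / b[:, None])


def savgol(s: SpectraSet, order: int = 2, window: int = SG_SMOOTH_WINDOW) -> SpectraSet:
    """Savitzky-Golay polynomial smoothing of each spectrum.

    A degree-``order`` polynomial is least-squares fit over a sliding window
    of ``window`` points; no derivative is taken.  The window must be odd
    and strictly longer than the polynomial order (with ``order == window-1``
    the fit interpolates and the filter is the identity).  Edge points are
    handled by evaluating the polynomial fit over the first/last full
    window rather than by padding the signal.
    """
    if window % 2 == 0:
        raise ValidationError(f"savgol window must be odd, got {window}")
    if order >= window:
        raise ValidationError(
            f"savgol polynomial order ({order}) must be less than window ({window})"
        )
    if order < 0:
        raise ValidationError(f"savgol order must be >= 0, got {order}")
    if window > s.n_features:
        raise ValidationError(
            f"savgol window ({window}) exceeds spectrum length ({s.n_features})"
        )
    smoothed = savgol_filter(s.absorbance, window_length=window, polyorder=order,
                             axis=1, mode="interp")
    return s.with_absorbance(smoothed)


def mean_center(
    s: SpectraSet, column_means: Union[str, np.ndarray] = "fit"
) -> tuple[SpectraSet, np.ndarray]:
    """Subtract per-wavelength column means.

    With ``column_means="fit"`` the means are learned from ``s`` itself
    (training mode); otherwise the supplied vector is used (test mode).
    Returns the centered set and the means that were applied.
    """
    if isinstance(column_means, str):
        if column_means != "fit":
            raise ValidationError(f"column_means must be 'fit' or a vector, got {column_means!r}")
        mu = s.absorbance.mean(axis=0)
    else:
        mu = np.asarray(column_means, dtype=float).ravel()
        if mu.size != s.n_features:
            raise ValidationError(
                f"column_means length {mu.size} != spectrum length {s.n_features}"
            )
    return s.with_absorbance(s.absorbance - mu), mu


# ----------------------------------------------------------------------
# configuration and trainable wrapper
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    """Which pretreatment to apply and its parameters.

    ``sg_window=None`` selects the method default (11 for ``sg_smooth``,
    53 for ``sg_filter``).  ``msc_reference="mean"`` uses the training-set
    column mean; an explicit vector may be supplied instead.
    """

    method: str = "sg_filter"
    sg_order: int = 2
    sg_window: Optional[int] = None
    msc_reference: Union[str, np.ndarray] = "mean"
    snv_ddof: int = 1

    def __post_init__(self) -> None:
        if self.method not in PREPROCESS_METHODS:
            raise ValidationError(
                f"unknown preprocessing method {self.method!r}; "
                f"expected one of {PREPROCESS_METHODS}"
            )
        if self.sg_window is not None:
            if self.sg_window % 2 == 0:
                raise ValidationError(f"sg_window must be odd, got {self.sg_window}")
            if self.sg_order >= self.sg_window:
                raise ValidationError(
                    f"sg_order ({self.sg_order}) must be less than sg_window ({self.sg_window})"
                )

    @property
    def effective_sg_window(self) -> int:
        if self.sg_window is not None:
            return self.sg_window
        return SG_FILTER_WINDOW if self.method == "sg_filter" else SG_SMOOTH_WINDOW


@dataclass
class FittedPreprocessor:
    """A pretreatment with its training-set state, applicable to new data.

    SNV and Savitzky-Golay are per-spectrum and carry no state; MSC stores
    the training reference spectrum and mean centering stores the training
    column means.  Fitting on training data only prevents test-set leakage.
    """

    config: PreprocessConfig
    reference: Optional[np.ndarray] = None  # msc reference or column means

    @classmethod
    def fit(cls, config: PreprocessConfig, train: SpectraSet) -> "FittedPreprocessor":
        ref = None
        if config.method == "msc":
            if isinstance(config.msc_reference, str):
                if config.msc_reference != "mean":
                    raise ValidationError(
                        f"msc_reference must be 'mean' or a vector, got {config.msc_reference!r}"
                    )
                ref = train.absorbance.mean(axis=0)
            else:
                ref = np.asarray(config.msc_reference, dtype=float).ravel()
        elif config.method == "mean_center":
            ref = train.absorbance.mean(axis=0)
        return cls(config=config, reference=ref)

    def transform(self, s: SpectraSet) -> SpectraSet:
        m = self.config.method
        if m == "none":
            return s.with_absorbance(s.absorbance)
        if m == "snv":
            return snv(s, ddof=self.config.snv_ddof)
        if m == "msc":
            return msc(s, reference=self.reference)
        if m == "mean_center":
            out, _ = mean_center(s, column_means=self.reference)
            return out
        if m in ("sg_smooth", "sg_filter"):
            return savgol(s, order=self.config.sg_order,
                          window=self.config.effective_sg_window)
        raise ValidationError(f"unknown preprocessing method {m!r}")
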