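"""Synthetic NIR spectra with known class structure.

Real NIR absorbance curves of fruit samples over 900-1700 nm are smooth
baselines with a small number of broad absorption bands (here the C-H band
near 1180 nm and the water/O-H band near 1430 nm), distorted per sample by
multiplicative and additive scatter and by instrument noise.  The generator
emulates exactly that structure with known ground truth, so every stage of
the pipeline (scatter correction, smoothing, PCA, discriminant extraction,
classification) can be exercised and validated without access to a real
spectrometer.

Each class gets its own smooth quadratic baseline and its own band
intensities, both drawn once per class; each sample then receives an affine
scatter distortion ``x <- m*x + a`` and i.i.d. Gaussian noise per point.
Setting ``class_effect_scale = 0`` removes every between-class difference;
setting the three standard deviations to zero makes the generator fully
deterministic within a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraSet, ValidationError

__all__ = ["GeneratorConfig", "generate_spectra", "default_wavelengths"]

#: number of spectral points on the default grid (portable NIR spectrometers
#: covering 900-1700 nm commonly digitise to a few hundred points)
_DEFAULT_N_POINTS = 228

# shared spectrum shape: quadratic baseline coefficients over the unit
# wavelength axis, and band heights for the default two peaks
_BASE_COEFS = (0.55, 0.25, -0.10)
_BASE_HEIGHTS = {1180.0: 0.25, 1430.0: 0.45}
_FALLBACK_HEIGHT = 0.35
# class effect on the baseline: full strength on the intercept (varieties
# of one fruit differ most visibly in overall absorbance level), quarter
# strength on slope and curvature
_BASELINE_EFFECT_RATIOS = (1.0, 0.25, 0.25)


def default_wavelengths() -> np.ndarray:
    """900-1700 nm sampled at 228 points (step ~3.5 nm)."""
    return np.linspace(900.0, 1700.0, _DEFAULT_N_POINTS)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic spectra generator.

    Attributes
    ----------
    n_classes, n_per_class:
        Balanced design: ``n_classes * n_per_class`` samples in total.
    wavelengths:
        Strictly increasing grid in nm.
    peak_centers, peak_width_nm:
        Gaussian absorption bands shared by all classes; class identity
        enters through per-class band-height offsets.
    class_effect_scale:
        Standard deviation of the per-class band-height offsets (absorbance
        units).  The per-class baseline also deviates by this much in its
        intercept and by a quarter of it in slope and curvature.  Zero
        means all classes share one mean spectrum.
    scatter_mult_sd, scatter_add_sd:
        Per-sample multiplicative slope (around 1) and additive offset
        (around 0) emulating particle-size/path-length scatter.
    noise_sd:
        I.i.d. Gaussian noise per spectral point.
    seed:
        Generator seed; identical config and seed give bit-identical output.
    """

    n_classes: int = 5
    n_per_class: int = 60
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    peak_centers: tuple[float, ...] = (1180.0, 1430.0)
    peak_width_nm: float = 50.0
    class_effect_scale: float = 0.08
    scatter_mult_sd: float = 0.02
    scatter_add_sd: float = 0.01
    noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "wavelengths", np.asarray(self.wavelengths, dtype=float).ravel()
        )
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_per_class < 2:
            raise ValidationError(f"n_per_class must be >= 2, got {self.n_per_class}")
        if self.wavelengths.size < 2 or not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing (length >= 2)")
        if self.peak_width_nm <= 0:
            raise ValidationError(f"peak_width_nm must be > 0, got {self.peak_width_nm}")
        for name in ("class_effect_scale", "scatter_mult_sd", "scatter_add_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")


def _base_heights(peak_centers: tuple[float, ...]) -> np.ndarray:
    return np.array([_BASE_HEIGHTS.get(c, _FALLBACK_HEIGHT) for c in peak_centers])


def generate_spectra(config: GeneratorConfig) -> SpectraSet:
    """Draw a balanced, labelled synthetic spectra set.

    The random stream is consumed in a fixed order -- all class-level draws
    first (baseline coefficients, then band-height offsets, class by class),
    then sample-level draws in class-major order (scatter slope, scatter
    offset, noise vector) -- so output is reproducible bit-for-bit for a
    given config and seed.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths
    t = (wl - wl[0]) / (wl[-1] - wl[0])  # unit wavelength axis
    n_peaks = len(config.peak_centers)
    base_heights = _base_heights(config.peak_centers)

    # class-level draws (fixed order: coefficients for all classes, then heights)
    coef_dev = rng.standard_normal((config.n_classes, 3))
    height_dev = rng.standard_normal((config.n_classes, n_peaks))
    coefs = (
        np.asarray(_BASE_COEFS)
        + config.class_effect_scale * np.asarray(_BASELINE_EFFECT_RATIOS) * coef_dev
    )
    heights = base_heights + config.class_effect_scale * height_dev

    bands = np.exp(
        -0.5
        * ((wl[None, :] - np.asarray(config.peak_centers)[:, None]) / config.peak_width_nm) ** 2
    )  # n_peaks x d

    rows = []
    labels = []
    for j in range(config.n_classes):
        clean = coefs[j, 0] + coefs[j, 1] * t + coefs[j, 2] * t**2 + heights[j] @ bands
        for _ in range(config.n_per_class):
            m = 1.0 + config.scatter_mult_sd * rng.standard_normal()
            a = config.scatter_add_sd * rng.standard_normal()
            x = m * clean + a
            x = x + config.noise_sd * rng.standard_normal(wl.size)
            rows.append(x)
            labels.append(j)

    return SpectraSet(
        wavelengths=wl.copy(),
        absorbance=np.vstack(rows),
        labels=np.asarray(labels),
    )
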