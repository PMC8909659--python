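"""Shared fixtures: small deterministic score sets and generator configs."""

from __future__ import annotations

import numpy as np
import pytest

from filda import GeneratorConfig, SpectraSet


def make_scores(n_per_class=10, c=3, k=4, spread=1.0, sep=3.0, seed=0) -> SpectraSet:
    """Labelled Gaussian blobs in a k-dimensional score space."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=sep, size=(c, k))
    rows, labels = [], []
    for j in range(c):
        rows.append(centers[j] + spread * rng.standard_normal((n_per_class, k)))
        labels.extend([j] * n_per_class)
    return SpectraSet(
        wavelengths=np.arange(k, dtype=float),
        absorbance=np.vstack(rows),
        labels=np.asarray(labels),
    )


@pytest.fixture
def blobs() -> SpectraSet:
    return make_scores()


@pytest.fixture
def easy_config() -> GeneratorConfig:
    """Designed-separable spectra: class effects dwarf every noise source."""
    return GeneratorConfig(
        class_effect_scale=0.3,
        noise_sd=0.005,
        scatter_mult_sd=0.01,
        scatter_add_sd=0.005,
        seed=1,
    )
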