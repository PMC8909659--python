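"""Pretreatment operators: hand-computed cases, oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filda import (
    FittedPreprocessor,
    GeneratorConfig,
    PreprocessConfig,
    SpectraSet,
    ValidationError,
    generate_spectra,
    mean_center,
    msc,
    savgol,
    snv,
)


def rowset(*rows, labels=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n, d = rows.shape
    return SpectraSet(
        wavelengths=np.arange(d, dtype=float),
        absorbance=rows,
        labels=np.zeros(n, dtype=int) if labels is None else labels,
    )


# ----------------------------------------------------------------------
# SNV
# ----------------------------------------------------------------------

def test_snv_hand_case_and_idempotence():
    out = snv(rowset([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0], atol=1e-14)
    again = snv(out)
    np.testing.assert_allclose(again.absorbance, out.absorbance, atol=1e-12)


def test_snv_constant_row_errors_with_sample_id():
    s = rowset([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    with pytest.raises(ValidationError, match="s0001"):
        snv(s)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(-50, 50), min_size=4, max_size=12),
    st.floats(-5, 5),
    st.floats(0.1, 10),
)
def test_snv_invariant_to_positive_affine_transforms(values, shift, scale):
    x = np.asarray(values)
    if x.std(ddof=1) < 1e-6:
        return  # constant rows are rejected by design
    base = snv(rowset(x))
    moved = snv(rowset(scale * x + shift))
    np.testing.assert_allclose(moved.absorbance, base.absorbance, atol=1e-8)


# ----------------------------------------------------------------------
# MSC
# ----------------------------------------------------------------------

def test_msc_reference_fixed_points():
    ref = np.array([0.1, 0.4, 0.9, 0.5, 0.2])
    s = rowset(ref, 2.0 * ref + 3.0)
    out = msc(s, reference=ref)
    np.testing.assert_allclose(out.absorbance[0], ref, atol=1e-12)
    np.testing.assert_allclose(out.absorbance[1], ref, atol=1e-12)


def test_msc_matches_normal_equations_oracle():
    rng = np.random.default_rng(7)
    ref = rng.uniform(0.2, 1.0, size=5)
    x = rng.uniform(0.1, 1.2, size=5)
    # brute-force least squares for x ~ a + b*ref via the design matrix
    design = np.column_stack([np.ones(5), ref])
    (a, b), *_ = np.linalg.lstsq(design, x, rcond=None)
    expected = (x - a) / b
    out = msc(rowset(x), reference=ref)
    np.testing.assert_allclose(out.absorbance[0], expected, atol=1e-12)


def test_msc_removes_generator_scatter_exactly_without_noise():
    """x = m*clean + a regressed on the clean spectrum inverts exactly."""
    cfg = GeneratorConfig(
        n_classes=2, n_per_class=5, class_effect_scale=0.0,
        scatter_mult_sd=0.1, scatter_add_sd=0.05, noise_sd=0.0, seed=3,
    )
    clean = generate_spectra(
        GeneratorConfig(
            n_classes=2, n_per_class=5, class_effect_scale=0.0,
            scatter_mult_sd=0.0, scatter_add_sd=0.0, noise_sd=0.0, seed=3,
        )
    ).absorbance[0]
    scattered = generate_spectra(cfg)
    corrected = msc(scattered, reference=clean)
    np.testing.assert_allclose(
        corrected.absorbance, np.tile(clean, (10, 1)), atol=1e-10
    )


def test_msc_zero_slope_errors():
    ref = np.array([0.0, 1.0, 2.0, 3.0])
    with pytest.raises(ValidationError, match="s0000"):
        msc(rowset([1.0, 1.0, 1.0, 1.0]), reference=ref)


# ----------------------------------------------------------------------
# Savitzky-Golay
# ----------------------------------------------------------------------

@pytest.mark.parametrize("window", [5, 11, 53])
def test_savgol_reproduces_quadratics(window):
    i = np.arange(100, dtype=float)
    quad = 0.3 + 0.02 * i - 0.001 * i**2
    out = savgol(rowset(quad), order=2, window=window)
    assert np.max(np.abs(out.absorbance[0] - quad)) <= 1e-9


def test_savgol_interpolating_order_is_identity():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(40)
    out = savgol(rowset(x), order=6, window=7)
    np.testing.assert_allclose(out.absorbance[0], x, atol=1e-8)


def test_savgol_reduces_white_noise_variance():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(228)
    out = savgol(rowset(x), order=2, window=53)
    assert out.absorbance[0].var(ddof=1) < x.var(ddof=1)


@pytest.mark.parametrize(
    "order, window", [(2, 10), (5, 5), (2, 300)]
)
def test_savgol_rejects_bad_parameters(order, window):
    with pytest.raises(ValidationError):
        savgol(rowset(np.arange(228.0)), order=order, window=window)


# ----------------------------------------------------------------------
# mean centering
# ----------------------------------------------------------------------

def test_mean_center_hand_case_and_fit_mode():
    s = rowset([1.0, 3.0], [3.0, 5.0])
    out, mu = mean_center(s, "fit")
    np.testing.assert_allclose(mu, [2.0, 4.0])
    np.testing.assert_allclose(out.absorbance, [[-1.0, -1.0], [1.0, 1.0]])
    assert np.max(np.abs(out.absorbance.mean(axis=0))) <= 1e-12
    again, _ = mean_center(out, "fit")
    np.testing.assert_allclose(again.absorbance, out.absorbance)


def test_mean_center_length_mismatch():
    with pytest.raises(ValidationError, match="length"):
        mean_center(rowset([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


# ----------------------------------------------------------------------
# shared contracts
# ----------------------------------------------------------------------

@pytest.mark.parametrize("method", ["snv", "msc", "mean_center", "sg_smooth", "sg_filter"])
def test_operators_preserve_shape_labels_wavelengths_order(method):
    s = generate_spectra(GeneratorConfig(n_classes=2, n_per_class=4, seed=9))
    fitted = FittedPreprocessor.fit(PreprocessConfig(method=method), s)
    out = fitted.transform(s)
    assert out.absorbance.shape == s.absorbance.shape
    assert np.array_equal(out.labels, s.labels)
    assert np.array_equal(out.wavelengths, s.wavelengths)
    assert out.sample_ids == s.sample_ids


def test_fitted_preprocessor_state_comes_from_training_set():
    train = generate_spectra(GeneratorConfig(n_classes=2, n_per_class=4, seed=1))
    fitted = FittedPreprocessor.fit(PreprocessConfig(method="msc"), train)
    np.testing.assert_allclose(fitted.reference, train.absorbance.mean(axis=0))
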