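"""Pretreatments: MSC, Savitzky-Golay, derivatives, logarithm, dispatcher."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brixcal.containers import SpectraMatrix
from brixcal.preprocess import (
    PreprocessMethod,
    apply_preprocessing,
    derivative,
    log_transform,
    msc,
    savitzky_golay,
)


class TestMSC:
    def test_reference_itself_maps_to_reference(self):
        m = np.array([0.3, 0.4, 0.5, 0.45, 0.35])
        out, ref = msc(m[None, :], m)
        assert np.allclose(out[0], m)

    def test_affine_distortion_removed_exactly(self):
        m = np.array([0.28, 0.40, 0.52, 0.48, 0.36])
        x = 1.0 + 2.0 * m
        out, _ = msc(x[None, :], m)
        assert np.allclose(out[0], m, atol=1e-12)

    def test_matches_closed_form_simple_regression(self):
        x = np.array([0.30, 0.42, 0.55, 0.50, 0.38])
        m = np.array([0.28, 0.40, 0.52, 0.48, 0.36])
        b, a = np.polyfit(m, x, 1)  # x ~ a + b m
        expected = (x - a) / b
        out, _ = msc(x[None, :], m)
        assert np.allclose(out[0], expected, atol=1e-12)

    @given(
        a=st.floats(-2, 2), b=st.floats(0.2, 5.0),
        flip=st.booleans(),
    )
    @settings(max_examples=40, deadline=None)
    def test_scatter_invariance_property(self, a, b, flip):
        # msc(a + b*x; m) == msc(x; m) for any affine distortion, b != 0
        rng = np.random.default_rng(99)
        m = np.linspace(0.2, 0.8, 12) + 0.05 * np.sin(np.arange(12))
        x = m + 0.02 * rng.standard_normal(12)
        b_signed = -b if flip else b
        base, _ = msc(x[None, :], m)
        distorted, _ = msc((a + b_signed * x)[None, :], m)
        assert np.allclose(base, distorted, atol=1e-9)

    def test_default_reference_is_training_mean_and_is_reused(self):
        rng = np.random.default_rng(0)
        X = 0.5 + 0.1 * rng.standard_normal((8, 10))
        _, ref = msc(X)
        assert np.allclose(ref, X.mean(axis=0))
        # transforming other data with this reference does not refit it
        Y = 0.5 + 0.1 * rng.standard_normal((4, 10))
        _, ref2 = msc(Y, ref)
        assert np.array_equal(ref, ref2)

    def test_zero_slope_sample_identified(self):
        m = np.linspace(0.2, 0.8, 6)
        X = np.vstack([m, np.full(6, 0.5)])  # flat sample: slope ~ 0
        with pytest.raises(ValueError, match="sample index 1"):
            msc(X, m)


class TestSavitzkyGolay:
    @pytest.mark.parametrize("window,polyorder", [(5, 2), (11, 2), (11, 3)])
    def test_polynomial_identity(self, window, polyorder):
        i = np.arange(60, dtype=float)
        X = np.vstack([2.0 + 0.3 * i, 1.0 - 0.05 * i + 0.002 * i**2])
        out = savitzky_golay(X, window, polyorder)
        assert np.allclose(out, X, atol=1e-8)

    def test_constant_unchanged(self):
        X = np.full((3, 30), 0.7)
        assert np.allclose(savitzky_golay(X, 7, 2), X, atol=1e-12)

    def test_impulse_center_weights_match_local_lsq_oracle(self):
        # response to a centred impulse reproduces the 5-point quadratic
        # least-squares smoother weights
        x = np.zeros(11)
        x[5] = 1.0
        out = savitzky_golay(x[None, :], 5, 2)[0]
        pts = np.arange(-2.0, 3.0)
        # direct LSQ: weight of centre point in fitting a quadratic
        V = np.vander(pts, 3, increasing=True)
        H = V @ np.linalg.inv(V.T @ V) @ V.T  # hat matrix; centre row = weights
        weights = H[2]
        assert np.allclose(out[3:8], weights[::-1], atol=1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros((1, 20)), 4, 2)
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros((1, 20)), 5, 5)
        with pytest.raises(ValueError):
            savitzky_golay(np.zeros((1, 6)), 7, 2)


class TestDerivative:
    def test_linear_spectrum_constant_first_derivative(self, grid):
        X = (0.001 * grid + 0.1)[None, :]
        d = derivative(X, grid, order=1)
        assert np.allclose(d, 0.001, atol=1e-12)

    def test_quadratic_constant_second_derivative(self, grid):
        a = 3e-6
        X = (a * grid**2)[None, :]
        dd = derivative(X, grid, order=2)
        interior = dd[0, 2:-2]
        assert np.allclose(interior, 2 * a, rtol=1e-6)

    def test_interior_matches_local_polynomial_oracle(self):
        # non-uniform 7-band grid; the 3-point interior stencil equals the
        # derivative of the quadratic through the three neighbouring points
        rng = np.random.default_rng(5)
        g = np.sort(rng.uniform(400, 900, 7))
        x = rng.standard_normal(7)
        d = derivative(x[None, :], g, order=1)[0]
        for j in range(1, 6):
            c = np.polynomial.polynomial.polyfit(g[j - 1 : j + 2], x[j - 1 : j + 2], 2)
            oracle = c[1] + 2 * c[2] * g[j]
            assert np.isclose(d[j], oracle, atol=1e-9)

    def test_second_derivative_consistent_with_twice_first(self):
        g = np.linspace(0.0, np.pi, 200)
        x = np.sin(g)[None, :]
        dd = derivative(x, g, order=2)
        d2 = derivative(derivative(x, g, 1), g, 1)
        assert np.allclose(dd, d2, atol=1e-12)  # order=2 is defined this way
        assert np.allclose(dd[0, 5:-5], -np.sin(g[5:-5]), atol=1e-3)

    def test_too_few_bands(self):
        with pytest.raises(ValueError):
            derivative(np.zeros((1, 2)), np.array([1.0, 2.0]), order=2)


class TestLogTransform:
    @pytest.mark.parametrize(
        "r,expected", [(1.0, 0.0), (0.1, 1.0), (0.0, 6.0)]
    )
    def test_reference_values(self, r, expected):
        out = log_transform(np.array([[r]]), epsilon=1e-6)
        assert np.isclose(out[0, 0], expected)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            log_transform(np.ones((1, 3)), epsilon=0.0)


class TestDispatcher:
    def test_all_transforms_preserve_shape(self, small_spectra):
        for tag in ("MSC_A", "SG_A", "dA", "ddA", "lgA"):
            out, _ = apply_preprocessing(small_spectra, PreprocessMethod(tag))
            assert out.values.shape == small_spectra.values.shape
            assert np.array_equal(out.wavelengths, small_spectra.wavelengths)

    def test_msc_state_reused_on_test_set(self, small_spectra, rng):
        method = PreprocessMethod("MSC_A")
        _, state = apply_preprocessing(small_spectra, method)
        test = small_spectra.with_values(
            0.5 + 0.1 * rng.standard_normal(small_spectra.values.shape)
        )
        out_with_state, state2 = apply_preprocessing(test, method, state)
        assert np.array_equal(state["reference"], state2["reference"])
        # transforming test data without the calibration state differs
        out_refit, _ = apply_preprocessing(test, method)
        assert not np.allclose(out_with_state.values, out_refit.values)

    def test_sg_applied_identically_to_train_and_test(self, small_spectra):
        method = PreprocessMethod("SG_A", window=7, polyorder=2)
        train_out, state = apply_preprocessing(small_spectra, method)
        test_out, _ = apply_preprocessing(small_spectra, method, state)
        assert np.allclose(train_out.values, test_out.values)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown pretreatment"):
            PreprocessMethod("SNV")
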