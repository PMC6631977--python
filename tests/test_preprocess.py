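import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirdx import errors
from nirdx.preprocess import (
    PreprocessStrategy,
    derivative,
    fit_apply_strategy,
    mean_center,
    msc,
    norris_derivative,
    savgol_weights,
    savitzky_golay,
    snv,
)
from nirdx.spectra_io import WavenumberGrid


def brute_force_savgol_center_weight(window: int, polyorder: int) -> np.ndarray:
    """Independent oracle: solve the windowed least-squares fit explicitly.

    The smoothed center value is the fitted polynomial at offset 0; because
    the fit is linear in y, the weight of each window point is obtained by
    fitting a unit impulse at that point.
    """
    half = window // 2
    offsets = np.arange(-half, half + 1)
    weights = []
    for j in range(window):
        y = np.zeros(window)
        y[j] = 1.0
        coeffs = np.polynomial.polynomial.polyfit(offsets, y, polyorder)
        weights.append(coeffs[0])  # polynomial value at offset 0
    return np.asarray(weights)


class TestMeanCenter:
    def test_self_fit(self):
        X = np.array([[1.0, 3.0], [3.0, 5.0]])
        out, means = mean_center(X)
        np.testing.assert_array_equal(means, [2.0, 4.0])
        np.testing.assert_array_equal(out, [[-1.0, -1.0], [1.0, 1.0]])

    def test_apply_stored_means(self):
        out, _ = mean_center(np.array([[2.0, 4.0]]), fitted_mean=np.array([2.0, 4.0]))
        np.testing.assert_array_equal(out, [[0.0, 0.0]])

    def test_single_row_self_fit_is_zero(self):
        out, _ = mean_center(np.array([[5.0, -1.0, 2.0]]))
        np.testing.assert_array_equal(out, np.zeros((1, 3)))

    def test_mean_length_mismatch(self):
        with pytest.raises(errors.ShapeError):
            mean_center(np.ones((2, 3)), fitted_mean=np.ones(4))


class TestSNV:
    def test_closed_form_sample_sd(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_constant_spectrum_degenerate(self):
        with pytest.raises(errors.DegenerateSpectrumError):
            snv(np.full(5, 2.0))

    @given(
        arrays(
            float,
            st.tuples(st.integers(1, 4), st.integers(3, 12)),
            elements=st.floats(-10, 10, allow_nan=False),
        ).filter(lambda x: np.all(x.std(axis=1) > 1e-6))
    )
    def test_idempotent_and_normalized(self, X):
        once = snv(X)
        np.testing.assert_allclose(snv(once), once, atol=1e-10)
        np.testing.assert_allclose(once.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(once.std(axis=1, ddof=1), 1.0, atol=1e-10)


class TestMSC:
    def test_affine_recovery(self):
        rng = np.random.default_rng(0)
        reference = rng.uniform(0.2, 0.8, size=50)
        x = 2.0 + 3.0 * reference
        np.testing.assert_allclose(msc(x, reference), reference, atol=1e-10)

    def test_identity_on_reference(self):
        reference = np.linspace(0.1, 0.9, 20)
        np.testing.assert_allclose(msc(reference, reference), reference, atol=1e-12)

    def test_zero_slope_degenerate(self):
        reference = np.linspace(0.0, 1.0, 11)
        flipped_plus_const = np.ones(11)  # no covariance with the reference
        with pytest.raises(errors.DegenerateFitError):
            msc(flipped_plus_const, reference)


class TestDerivatives:
    def test_first_derivative_of_linear(self):
        out = derivative(np.array([[0.0, 1.0, 2.0, 3.0]]), 1)
        np.testing.assert_array_equal(out, [[1.0, 1.0, 1.0, 1.0]])

    def test_second_derivative_of_quadratic(self):
        k = np.arange(5.0)
        out = derivative((k**2)[np.newaxis, :], 2)
        np.testing.assert_allclose(out, np.full((1, 5), 2.0))

    def test_two_point_input_errors(self):
        with pytest.raises(errors.ShapeError):
            derivative(np.array([[1.0, 2.0]]), 1)

    def test_nonuniform_grid_rejected(self):
        grid = WavenumberGrid(np.array([9000.0, 8000.0, 6600.0, 6000.0]))
        with pytest.raises(errors.ParameterError):
            derivative(np.ones((1, 4)), 1, grid)


class TestSavitzkyGolay:
    def test_weights_match_brute_force_oracle(self):
        expected = np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0
        np.testing.assert_allclose(savgol_weights(5, 2), expected, atol=1e-12)
        np.testing.assert_allclose(
            brute_force_savgol_center_weight(5, 2), expected, atol=1e-12
        )

    @pytest.mark.parametrize("window,polyorder", [(5, 2), (7, 3), (11, 3)])
    def test_weights_equal_oracle_generally(self, window, polyorder):
        np.testing.assert_allclose(
            savgol_weights(window, polyorder),
            brute_force_savgol_center_weight(window, polyorder),
            atol=1e-10,
        )

    def test_polynomial_reproduced_exactly(self):
        x = np.arange(30.0)
        poly = 0.5 - 0.3 * x + 0.02 * x**2
        out = savitzky_golay(poly[np.newaxis, :], 7, 2)
        np.testing.assert_allclose(out[0], poly, atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(errors.ParameterError):
            savitzky_golay(np.ones((1, 10)), 4, 2)

    def test_full_order_window_is_identity_interior(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 25))
        out = savitzky_golay(X, 5, 4)
        np.testing.assert_allclose(out[:, 2:-2], X[:, 2:-2], atol=1e-8)


class TestNorris:
    def test_reduces_to_plain_first_difference(self):
        x = np.array([[0.0, 1.0, 4.0, 9.0, 16.0]])
        out = norris_derivative(x, segment=1, gap=1, order=1)
        np.testing.assert_allclose(out[0, :-1], np.diff(x[0]))

    def test_linear_input_gives_constant_interior(self):
        x = np.linspace(0, 10, 40)[np.newaxis, :]
        out = norris_derivative(x, segment=5, gap=3, order=1)
        interior = out[0, 3:-5]
        np.testing.assert_allclose(interior, interior[0], atol=1e-9)

    def test_constant_spectrum_gives_zeros(self):
        out = norris_derivative(np.full((1, 20), 3.0), segment=3, gap=1, order=1)
        np.testing.assert_allclose(out, 0.0)

    def test_segment_gap_too_large(self):
        with pytest.raises(errors.ParameterError):
            norris_derivative(np.ones((1, 5)), segment=5, gap=2, order=1)


class TestStrategy:
    def test_parse_and_str_roundtrip(self):
        s = PreprocessStrategy.parse("SNV+NDS(5,5)+FD+MC")
        assert [step.name for step in s.steps] == ["SNV", "NDS", "FD", "MC"]
        assert str(s) == "SNV+NDS(5,5)+FD+MC"

    def test_mc_must_be_last(self):
        with pytest.raises(errors.ParameterError):
            PreprocessStrategy.parse("MC+SNV")

    def test_duplicate_operator_rejected(self):
        with pytest.raises(errors.ParameterError):
            PreprocessStrategy.parse("SNV+SNV+MC")

    def test_plain_mc_strategy(self):
        X = np.array([[1.0, 3.0], [3.0, 5.0]])
        out, _, _ = fit_apply_strategy("MC", X)
        np.testing.assert_array_equal(out, [[-1.0, -1.0], [1.0, 1.0]])

    def test_snv_mc_composition_matches_hand_result(self):
        # row-wise SNV first, then column centering with calibration means
        X = np.array([[1.0, 2.0, 3.0], [5.0, 3.0, 1.0], [2.0, 2.0, 5.0]])
        expected = snv(X) - snv(X).mean(axis=0)
        out, _, _ = fit_apply_strategy("SNV+MC", X)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_msc_mc_fixed_point_on_calibration_mean(self):
        # calibration rows exactly affine in the reference -> the calibration
        # mean spectrum transforms to the zero vector
        rng = np.random.default_rng(3)
        reference = rng.uniform(0.2, 0.8, size=30)
        X_cal = np.stack([a + b * reference for a, b in [(0.1, 1.2), (-0.2, 0.8), (0.3, 1.5)]])
        _, out_new, _ = fit_apply_strategy("MSC+MC", X_cal, X_cal.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(out_new, 0.0, atol=1e-10)

    def test_leakage_guard_state_frozen_after_fit(self):
        rng = np.random.default_rng(4)
        X_cal = rng.uniform(0.1, 1.0, size=(6, 20))
        _, fitted = PreprocessStrategy.parse("MSC+MC").fit(X_cal)
        state_before = {k: v.copy() for k, v in fitted.fitted_state.items()}
        out1 = fitted.apply(rng.uniform(size=(3, 20)))
        out2 = fitted.apply(rng.uniform(10, 11, size=(3, 20)))
        for key, value in state_before.items():
            np.testing.assert_array_equal(fitted.fitted_state[key], value)
        assert not np.allclose(out1, out2)  # different data, same state

    @pytest.mark.parametrize(
        "strategy", ["MC", "SNV", "MSC", "FD+MC", "SD+MC", "SGS(11,3)+MC", "NDS(5,5)+FD+MC"]
    )
    def test_all_strategies_shape_preserving(self, strategy):
        rng = np.random.default_rng(5)
        X = rng.uniform(0.1, 1.0, size=(4, 60))
        out, out_new, _ = fit_apply_strategy(strategy, X, X[:2])
        assert out.shape == X.shape
        assert out_new.shape == (2, 60)
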