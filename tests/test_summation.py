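"""Model 0 / Model 1 fits, the uncentered scatter statistic, linearity calls."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from casum.patterns import StimulusPattern, design_matrix, enumerate_patterns
from casum.response import COLUMNS, ResponseMatrix
from casum.slice_model import run_experiment
from casum.summation import (
    IOCurve,
    analyze_matrix,
    fit_io,
    fit_model0,
    io_curve,
    model1_residual,
    origin_slope,
    predict_model1,
    scatter_r2,
    single_electrode_responses,
    SingleElectrodeResponses,
)


def _matrix_from_outputs(outputs, n_el):
    """ResponseMatrix with one trial whose responses follow `outputs(pattern)`."""
    records = []
    for pat in enumerate_patterns(n_el):
        records.append({
            "group_id": "g0", "pattern_id": pat.pattern_id,
            "pattern_bits": pat.bits_string, "trial": 0,
            "peak_dff": float(outputs(pat)),
        })
    return ResponseMatrix(pd.DataFrame.from_records(records, columns=COLUMNS), n_el)


class TestFitModel0:
    def test_recovers_exact_linear_weights(self):
        w = np.array([1.0, 2.0, 3.0])
        m = _matrix_from_outputs(lambda p: p.as_array() @ w, 3)
        fit = fit_model0(m)["g0"]
        np.testing.assert_allclose(fit.weights, w, atol=1e-12)
        assert fit.residual == pytest.approx(0.0, abs=1e-20)

    def test_all_zero_outputs_give_zero_weights(self):
        m = _matrix_from_outputs(lambda p: 0.0, 3)
        fit = fit_model0(m)["g0"]
        np.testing.assert_allclose(fit.weights, 0.0, atol=1e-15)
        assert fit.residual == 0.0

    def test_matches_normal_equations_oracle_on_thresholded_group(self):
        """Thresholded (nonlinear) data: compare with an independent pseudo-inverse."""
        thresholds = np.array([0.8, 1.4, 2.1])
        amps = np.array([0.03, 0.05, 0.02])
        w_true = np.array([[0.9, 0.1, 0.4], [0.2, 1.1, 0.3], [0.5, 0.6, 0.7]])

        def out(p):
            drives = w_true @ p.as_array()
            return float(amps @ (drives > thresholds))

        m = _matrix_from_outputs(out, 3)
        fit = fit_model0(m)["g0"]
        X = design_matrix(enumerate_patterns(3))
        y = np.array([out(p) for p in enumerate_patterns(3)])
        w_oracle = np.linalg.pinv(X) @ y
        np.testing.assert_allclose(fit.weights, w_oracle, atol=1e-6)
        assert fit.residual == pytest.approx(np.sum((y - X @ w_oracle) ** 2), abs=1e-12)

    def test_rank_deficient_design_raises(self):
        m = _matrix_from_outputs(lambda p: float(sum(p.bits)), 3)
        m.data = m.data[m.data["pattern_id"].isin([1, 2, 3])]  # e3 never used alone
        with pytest.raises(ValueError, match="rank"):
            fit_model0(m)


class TestPredictModel1:
    @pytest.mark.parametrize(
        "bits,expected",
        [((1, 0, 1), 0.7), ((0, 1, 0), 0.0), ((1, 1, 1), 0.7)],
    )
    def test_sser_sums_active_electrodes(self, bits, expected):
        ser = SingleElectrodeResponses("g", (0.2, 0.0, 0.5), (False, True, False))
        assert predict_model1(ser, StimulusPattern(bits)) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        ser = SingleElectrodeResponses("g", (0.2, 0.3), (False, False))
        with pytest.raises(ValueError):
            predict_model1(ser, StimulusPattern((1, 0, 1)))

    def test_zero_assignment_of_silent_electrodes(self):
        # electrode 2 never drives a response -> assigned 0
        m = _matrix_from_outputs(lambda p: 0.4 * p.bits[0] + 0.1 * p.bits[2], 3)
        ser = single_electrode_responses(m)["g0"]
        assert ser.responses == pytest.approx((0.4, 0.0, 0.1))
        assert ser.zero_assigned == (False, True, False)


class TestIOCurve:
    def test_model0_perfect_line(self):
        w = np.array([0.2, 0.5, 0.3])
        m = _matrix_from_outputs(lambda p: p.as_array() @ w, 3)
        curve = io_curve(m, "model0")["g0"]
        np.testing.assert_allclose(curve.predicted, curve.actual, atol=1e-12)

    def test_model1_excludes_joint_zero_points(self):
        # electrode 2 silent: its singleton pattern is (0,0) under model1
        m = _matrix_from_outputs(lambda p: 0.4 * p.bits[0] + 0.1 * p.bits[2], 3)
        curve = io_curve(m, "model1")["g0"]
        assert curve.n_excluded == 1
        assert len(curve.predicted) == 6

    def test_model1_normalizes_mean_actual_to_one(self):
        m = _matrix_from_outputs(lambda p: 0.1 + 0.05 * sum(p.bits), 3)
        curve = io_curve(m, "model1")["g0"]
        assert curve.actual.mean() == pytest.approx(1.0)

    def test_model1_single_axis_normalization_option(self):
        m = _matrix_from_outputs(lambda p: 0.1 * sum(p.bits), 3)
        both = io_curve(m, "model1", normalize_both_axes=True)["g0"]
        single = io_curve(m, "model1", normalize_both_axes=False)["g0"]
        np.testing.assert_allclose(both.actual, single.actual)
        mean_actual = 0.1 * np.mean([sum(p.bits) for p in enumerate_patterns(3)])
        np.testing.assert_allclose(single.predicted, both.predicted * mean_actual)


class TestFitIO:
    def test_exact_line_gives_unit_r2_and_slope(self):
        x = np.linspace(0.1, 2.0, 10)
        fit = fit_io((x, 1.7 * x))
        assert fit.slope == pytest.approx(1.7, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.linear
        lo, hi = fit.slope_ci95
        assert lo <= fit.slope <= hi

    def test_scatter_statistic_direct_evaluation(self):
        # actuals (1, 0) against fitted values (0.5, 0.5) at a fixed slope:
        # 1 - [(1-0.5)^2 + (0-0.5)^2] / (1^2 + 0^2) = 0.5
        r2 = scatter_r2(np.array([1.0, 1.0]), np.array([1.0, 0.0]), slope=0.5)
        assert r2 == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("target,expect_linear", [(0.76, True), (0.75, False)])
    def test_linearity_threshold_is_strict(self, target, expect_linear):
        # symmetric residual (+d, -d, 0) leaves the origin slope at 1;
        # solve for the d that puts the scatter statistic exactly at target
        from scipy.optimize import brentq

        x = np.array([1.0, 1.0, 1.0])

        def r2_minus_target(d):
            y = np.array([1.0 + d, 1.0 - d, 1.0])
            return scatter_r2(x, y, origin_slope(x, y)) - target

        d = brentq(r2_minus_target, 0.0, 0.99)
        fit = fit_io((x, np.array([1.0 + d, 1.0 - d, 1.0])))
        assert fit.r2 == pytest.approx(target, abs=1e-9)
        assert fit.linear is expect_linear

    def test_r2_in_unit_interval_for_ls_slope(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 40)
            x = rng.uniform(0.01, 2.0, n)
            y = rng.uniform(0.0, 2.0, n)
            r2 = scatter_r2(x, y, origin_slope(x, y))
            assert 0.0 <= r2 <= 1.0 + 1e-12

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_io((np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestOptimality:
    def test_model0_residual_never_exceeds_model1(self, noisy_matrix):
        """Model 0 minimizes the objective Model 1 evaluates with fixed weights."""
        res0 = {g: f.residual for g, f in fit_model0(noisy_matrix).items()}
        res1 = model1_residual(noisy_matrix)
        for gid in res0:
            assert res0[gid] <= res1[gid] + 1e-12


class TestPipelineRecovery:
    def test_noise_free_linear_groups_recover_slope_one(self, graded_slice):
        m = run_experiment(graded_slice, trials=1, seed=0)
        fits = analyze_matrix(m, "model0")
        assert fits["linear"].all()
        np.testing.assert_allclose(fits["slope"], 1.0, atol=1e-9)
        np.testing.assert_allclose(fits["r2"], 1.0, atol=1e-12)
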