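"""Gain/offset decomposition and slope-change tests across conditions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from casum.perturbation import (
    ConditionPair,
    TransformResult,
    analyze_pair,
    compare_conditions,
    potentiation_pct,
    slope_change_test,
    summarize_population,
)
from casum.slice_model import PerturbationSpec, run_experiment
from casum.summation import IOCurve, io_curve


def _shifted(matrix, mult=1.0, add=0.0):
    data = matrix.data.copy()
    data["peak_dff"] = mult * data["peak_dff"] + add
    return dataclasses.replace(matrix, data=data)


@pytest.fixture(scope="module")
def graded_matrix(graded_slice):
    return run_experiment(graded_slice, trials=1, seed=0)


class TestCompareConditions:
    def test_identity_pair(self, graded_matrix):
        pair = ConditionPair(graded_matrix, _shifted(graded_matrix), "none")
        fits, pooled = compare_conditions(pair)
        for f in fits.values():
            assert f.slope == pytest.approx(1.0, abs=1e-9)
            assert f.offset == pytest.approx(0.0, abs=1e-12)
            assert f.r2 == pytest.approx(1.0, abs=1e-12)
        assert pooled.slope == pytest.approx(1.0, abs=1e-9)

    def test_pure_additive_shift(self, graded_matrix):
        pair = ConditionPair(graded_matrix, _shifted(graded_matrix, add=0.3), "add")
        fits, pooled = compare_conditions(pair)
        for f in fits.values():
            assert f.slope == pytest.approx(1.0, abs=1e-9)
            assert f.offset == pytest.approx(0.3, abs=1e-9)
        assert pooled.offset == pytest.approx(0.3, abs=1e-9)

    def test_pure_multiplicative_change(self, graded_slice, graded_matrix):
        """scale_input on threshold-free groups is an exact gain change."""
        post = run_experiment(
            graded_slice, PerturbationSpec("scale_input", scale_a=0.75), trials=1, seed=0
        )
        pair = ConditionPair(graded_matrix, post, "scale")
        fits, pooled = compare_conditions(pair)
        for f in fits.values():
            assert f.slope == pytest.approx(0.75, abs=1e-9)
            assert f.offset == pytest.approx(0.0, abs=1e-9)
        assert pooled.slope == pytest.approx(0.75, abs=1e-9)

    def test_scaling_with_threshold_truncation(self, default_slice):
        """Sub-threshold truncation pulls the fitted slope below the factor
        and the offset to zero or below."""
        slc = dataclasses.replace(default_slice, noise_sd=0.0)
        pre = run_experiment(slc, trials=1, seed=0)
        post = run_experiment(slc, PerturbationSpec("scale_input", scale_a=0.75), trials=1, seed=0)
        _, pooled = compare_conditions(ConditionPair(pre, post, "scale"))
        assert pooled.slope < 1.0
        assert pooled.offset <= 1e-12

    def test_mismatched_pairs_rejected(self, graded_matrix, noisy_matrix):
        with pytest.raises(ValueError):
            ConditionPair(graded_matrix, noisy_matrix, "bad")


def _curve(predicted, actual):
    return IOCurve("g", "model1", np.asarray(predicted, float), np.asarray(actual, float), 0)


class TestSlopeChangeTest:
    def test_identical_points_not_changed(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 2.0, 31)
        y = x * rng.lognormal(0.0, 0.05, 31)
        p, changed, dropped = slope_change_test(_curve(x, y), _curve(x, y))
        assert not changed
        assert p == pytest.approx(1.0)
        assert dropped == 0

    def test_gain_half_detected_with_exact_log_shift(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.5, 2.0, 31)
        y = x * rng.lognormal(0.0, 0.05, 31)
        pre, post = _curve(x, y), _curve(x, 0.5 * y)
        la = np.log(y / x)
        lb = np.log(0.5 * y / x)
        assert np.mean(lb) - np.mean(la) == pytest.approx(np.log(0.5), abs=1e-12)
        p, changed, _ = slope_change_test(pre, post)
        assert changed and p < 1e-10

    def test_matches_independent_t_oracle(self):
        """p-values agree with a hand-coded pooled-variance Student's t."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n1, n2 = rng.integers(5, 31, size=2)
            x1, x2 = rng.uniform(0.5, 2.0, n1), rng.uniform(0.5, 2.0, n2)
            y1 = x1 * rng.lognormal(0.0, 0.2, n1)
            y2 = x2 * rng.lognormal(rng.normal(0, 0.2), 0.2, n2)
            p, _, _ = slope_change_test(_curve(x1, y1), _curve(x2, y2))
            a, b = np.log(y1 / x1), np.log(y2 / x2)
            sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
            t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / n1 + 1 / n2))
            p_oracle = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
            assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_detection_rate_of_gain_under_noise(self):
        """Monte Carlo power at gain 0.75 with multiplicative trial noise."""
        rng = np.random.default_rng(6)
        detected = []
        for _ in range(300):
            x = rng.uniform(0.5, 2.0, 31)
            y_pre = x * rng.lognormal(0.0, 0.15, 31)
            y_post = 0.75 * x * rng.lognormal(0.0, 0.15, 31)
            p, changed, _ = slope_change_test(_curve(x, y_pre), _curve(x, y_post))
            detected.append(changed)
        rate = np.mean(detected)
        # analytic power of the two-sample t at delta = log(0.75), sd 0.15, n = 31
        delta = -np.log(0.75) / (0.15 * np.sqrt(2 / 31))
        power = stats.nct.sf(stats.t.ppf(0.975, 60), df=60, nc=delta)
        assert rate == pytest.approx(power, abs=0.06)

    def test_zero_points_are_dropped_and_counted(self):
        pre = _curve([1.0, 1.0, 0.0, 1.0], [1.0, 0.0, 1.0, 1.1])
        post = _curve([1.0, 1.0, 1.0], [1.0, 0.9, 1.05])
        _, _, dropped = slope_change_test(pre, post)
        assert dropped == 2

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            slope_change_test(_curve([1.0], [1.0]), _curve([1.0, 2.0], [1.0, 2.0]))


class TestAnalyzePair:
    def test_inhibition_block_gives_positive_offset(self, default_slice):
        pre = run_experiment(default_slice, trials=3, seed=1)
        post = run_experiment(
            default_slice, PerturbationSpec("block_inhibition"), trials=3, seed=2
        )
        results = analyze_pair(ConditionPair(pre, post, "picrotoxin"))
        offsets = [r.cross_offset for r in results]
        assert np.mean(offsets) > 0
        unchanged = np.mean([not r.slope_changed for r in results])
        assert unchanged > 0.5

    def test_potentiation_pct_measures_singleton_increase(self, graded_slice):
        pre = run_experiment(graded_slice, trials=1, seed=0)
        post = run_experiment(
            graded_slice,
            PerturbationSpec("ltp", ltp_electrode=2, ltp_factor=1.5,
                             homeostatic_threshold_factor=1.0),
            trials=1, seed=0,
        )
        pots = potentiation_pct(ConditionPair(pre, post, "ltp"), electrode=2)
        # graded neurons: response on the tetanized electrode scales with weight
        for v in pots.values():
            assert v == pytest.approx(50.0, abs=1e-6)


def _result(gid, slope_pre=1.0, slope_post=1.0, offset=0.0, changed=False):
    return TransformResult(
        group_id=gid, cross_slope=1.0, cross_offset=offset, cross_r2=1.0,
        io_slope_pre=slope_pre, io_slope_post=slope_post,
        slope_changed=changed, p_value=1.0, ci_contains=True, n_dropped_log_points=0,
    )


class TestSummarizePopulation:
    def test_all_unchanged(self):
        results = [_result(f"g{i}") for i in range(5)]
        s = summarize_population(results)
        assert s.fraction_slope_unchanged == 1.0
        assert s.median_slope_change_pct == 0.0

    def test_uniform_25pct_slope_decrease(self):
        results = [_result(f"g{i}", slope_pre=1.0, slope_post=0.75) for i in range(8)]
        s = summarize_population(results)
        assert s.median_slope_change_pct == pytest.approx(-25.0)

    def test_offset_correlation_recovers_generating_relation(self):
        rng = np.random.default_rng(8)
        pot = {f"g{i}": float(rng.uniform(10, 200)) for i in range(60)}
        results = [
            _result(g, offset=0.001 * v + rng.normal(0, 0.02),
                    slope_pre=1.0, slope_post=1.0 - 0.001 * v + rng.normal(0, 0.05))
            for g, v in pot.items()
        ]
        s = summarize_population(results, potentiation=pot)
        # offset grows and slope falls with potentiation by construction
        assert s.pearson_r_offset > 0.5
        assert s.pearson_r_slope < -0.5
        assert s.pearson_p_offset < 0.01

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_population([])
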