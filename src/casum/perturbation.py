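"""Cross-condition transforms of input-output curves.

Given matched response matrices recorded before and after a network
perturbation (reduced stimulation current, inhibition block, LTP), this
module decomposes the change into gain (slope) and offset (intercept)
components and tests whether the I-O slope changed.

Two slope-change criteria are computed per group:

* a two-sample Student's t-test on ``log(actual / SSER)`` of the
  included points pre vs. post — this drives the ``slope_changed``
  boolean (changed iff p < 0.05);
* whether the post-condition through-origin I-O slope lies inside the
  pre-condition fit's 95% confidence interval (``ci_contains``),
  reported alongside.

The model-free comparison regresses post responses on pre responses
(ordinary least squares with intercept): a pure gain change shows as a
slope != 1 with zero offset, a pure additive change as slope 1 with a
non-zero offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .response import ResponseMatrix
from .summation import IOCurve, analyze_matrix, fit_io, io_curve, single_electrode_responses

logger = logging.getLogger(__name__)

SLOPE_CHANGE_ALPHA = 0.05


@dataclass(frozen=True)
class ConditionPair:
    """Matched pre/post response matrices for one perturbation."""

    pre: ResponseMatrix
    post: ResponseMatrix
    label: str = ""

    def __post_init__(self) -> None:
        if self.pre.n_electrodes != self.post.n_electrodes:
            raise ValueError("pre and post electrode counts differ")
        if self.pre.group_ids != self.post.group_ids:
            raise ValueError("pre and post group ids differ")
        if self.pre.pattern_ids != self.post.pattern_ids:
            raise ValueError("pre and post pattern sets differ")


@dataclass(frozen=True)
class CrossConditionFit:
    """OLS of post response against pre response for one group (or pooled)."""

    group_id: str
    slope: float
    offset: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class TransformResult:
    """Gain/offset decomposition and slope-change tests for one group."""

    group_id: str
    cross_slope: float
    cross_offset: float
    cross_r2: float
    io_slope_pre: float
    io_slope_post: float
    slope_changed: bool
    p_value: float
    ci_contains: bool
    n_dropped_log_points: int


@dataclass(frozen=True)
class PopulationSummary:
    """Cohort-level statistics over groups (possibly several slices)."""

    n_groups: int
    fraction_linear: float
    fraction_slope_unchanged: float
    median_slope_change_pct: float
    offset_mean_pct: float
    offset_sd_pct: float
    pearson_r_slope: float
    pearson_p_slope: float
    pearson_r_offset: float
    pearson_p_offset: float


def _ols_with_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def compare_conditions(
    pair: ConditionPair, detection_floor: float = 0.0
) -> tuple[dict[str, CrossConditionFit], CrossConditionFit]:
    """Per-group and pooled OLS of post vs. pre trial-mean responses.

    Model-free: no SSER or weight fit is involved.  Points with zero
    pre response are dropped (the pre condition carries no signal
    there); each group needs >= 3 remaining points.
    """
    agg_pre = pair.pre.aggregate()
    agg_post = pair.post.aggregate()
    fits: dict[str, CrossConditionFit] = {}
    all_x, all_y = [], []
    for gid in pair.pre.group_ids:
        x = agg_pre.loc[gid].sort_index()["peak_dff"].to_numpy()
        y = agg_post.loc[gid].sort_index()["peak_dff"].to_numpy()
        keep = x > detection_floor
        if keep.sum() < 3:
            logger.warning("group %s: fewer than 3 usable pre>0 points; skipped", gid)
            continue
        xs, ys = x[keep], y[keep]
        all_x.append(xs)
        all_y.append(ys)
        if np.ptp(xs) == 0:
            logger.warning("group %s: degenerate pre responses; skipped", gid)
            continue
        slope, offset, r2 = _ols_with_intercept(xs, ys)
        fits[gid] = CrossConditionFit(gid, slope, offset, r2, int(keep.sum()))
    if not all_x:
        raise ValueError("no group had enough usable points for the cross-condition fit")
    X = np.concatenate(all_x)
    Y = np.concatenate(all_y)
    slope, offset, r2 = _ols_with_intercept(X, Y)
    pooled = CrossConditionFit("__pooled__", slope, offset, r2, len(X))
    return fits, pooled


def _log_ratios(curve: IOCurve) -> tuple[np.ndarray, int]:
    """log(actual / predicted) over points where both are positive."""
    keep = (curve.actual > 0) & (curve.predicted > 0)
    dropped = int((~keep).sum())
    return np.log(curve.actual[keep] / curve.predicted[keep]), dropped


def slope_change_test(
    pre_curve: IOCurve,
    post_curve: IOCurve,
    paired: bool = False,
) -> tuple[float, bool, int]:
    """Student's t-test on log(actual/SSER) pre vs. post for one group.

    Returns ``(p_value, slope_changed, n_dropped)``.  ``paired=True``
    switches to a paired t-test on pattern-matched points (requires
    equal included point sets).
    """
    la, d1 = _log_ratios(pre_curve)
    lb, d2 = _log_ratios(post_curve)
    if len(la) < 2 or len(lb) < 2:
        raise ValueError("fewer than 2 usable points in one condition")
    if paired:
        if len(la) != len(lb):
            raise ValueError("paired test requires equal point counts")
        t = stats.ttest_rel(la, lb)
    else:
        t = stats.ttest_ind(la, lb)
    p = float(t.pvalue)
    if np.isnan(p):  # zero variance in both samples -> identical ratios
        p = 1.0
    return p, bool(p < SLOPE_CHANGE_ALPHA), d1 + d2


def analyze_pair(
    pair: ConditionPair,
    detection_floor: float = 0.0,
    paired_ttest: bool = False,
) -> list[TransformResult]:
    """Full per-group transform analysis of a condition pair."""
    cross, _ = compare_conditions(pair, detection_floor)
    curves_pre = io_curve(pair.pre, "model1", detection_floor)
    curves_post = io_curve(pair.post, "model1", detection_floor)
    results = []
    for gid in pair.pre.group_ids:
        if gid not in cross or gid not in curves_pre or gid not in curves_post:
            continue
        try:
            fit_pre = fit_io(curves_pre[gid])
            fit_post = fit_io(curves_post[gid])
            p, changed, dropped = slope_change_test(
                curves_pre[gid], curves_post[gid], paired=paired_ttest
            )
        except ValueError as exc:
            logger.warning("group %s: %s", gid, exc)
            continue
        lo, hi = fit_pre.slope_ci95
        results.append(
            TransformResult(
                group_id=gid,
                cross_slope=cross[gid].slope,
                cross_offset=cross[gid].offset,
                cross_r2=cross[gid].r2,
                io_slope_pre=fit_pre.slope,
                io_slope_post=fit_post.slope,
                slope_changed=changed,
                p_value=p,
                ci_contains=bool(lo <= fit_post.slope <= hi),
                n_dropped_log_points=dropped,
            )
        )
    if not results:
        raise ValueError("no group could be analyzed")
    return results


def potentiation_pct(pair: ConditionPair, electrode: int, detection_floor: float = 0.0) -> dict[str, float]:
    """% increase of the tetanized electrode's single-electrode response.

    Groups whose pre response on that electrode is zero are skipped
    (relative potentiation undefined).
    """
    ser_pre = single_electrode_responses(pair.pre, detection_floor)
    ser_post = single_electrode_responses(pair.post, detection_floor)
    out = {}
    for gid in pair.pre.group_ids:
        pre_v = ser_pre[gid].responses[electrode]
        post_v = ser_post[gid].responses[electrode]
        if pre_v > 0:
            out[gid] = 100.0 * (post_v - pre_v) / pre_v
    return out


def summarize_population(
    results: list[TransformResult],
    pair: Optional[ConditionPair] = None,
    potentiation: Optional[dict[str, float]] = None,
    detection_floor: float = 0.0,
) -> PopulationSummary:
    """Cohort statistics over per-group transform results.

    ``fraction_linear`` is the share of groups whose *post* I-O curve is
    classified linear.  Offsets are expressed as a percentage of each
    group's maximum pre-condition response (requires ``pair``).
    Pearson correlations of slope change and offset against
    ``potentiation`` (% increase on the tetanized electrode) are NaN
    when no potentiation mapping is supplied.
    """
    if not results:
        raise ValueError("no transform results to summarize")
    post_linear = []
    if pair is not None:
        fits_post = analyze_matrix(pair.post, "model1", detection_floor).set_index("group_id")
        post_linear = [
            bool(fits_post.loc[r.group_id, "linear"])
            for r in results
            if r.group_id in fits_post.index
        ]
    frac_linear = float(np.mean(post_linear)) if post_linear else float("nan")
    frac_unchanged = float(np.mean([not r.slope_changed for r in results]))
    slope_change_pct = np.array(
        [100.0 * (r.io_slope_post - r.io_slope_pre) / r.io_slope_pre for r in results]
    )
    median_change = float(np.median(slope_change_pct))

    if pair is not None:
        max_pre = pair.pre.max_response_per_group()
        offsets_pct = np.array(
            [100.0 * r.cross_offset / max_pre[r.group_id] for r in results if max_pre[r.group_id] > 0]
        )
    else:
        offsets_pct = np.array([100.0 * r.cross_offset for r in results])
    offset_mean = float(offsets_pct.mean()) if len(offsets_pct) else float("nan")
    offset_sd = float(offsets_pct.std(ddof=1)) if len(offsets_pct) > 1 else float("nan")

    r_slope = p_slope = r_off = p_off = float("nan")
    if potentiation:
        gids = [r.group_id for r in results if r.group_id in potentiation]
        if len(gids) >= 3:
            pot = np.array([potentiation[g] for g in gids])
            by_gid = {r.group_id: r for r in results}
            sc = np.array(
                [
                    100.0
                    * (by_gid[g].io_slope_post - by_gid[g].io_slope_pre)
                    / by_gid[g].io_slope_pre
                    for g in gids
                ]
            )
            off = np.array([by_gid[g].cross_offset for g in gids])
            if np.ptp(pot) > 0 and np.ptp(sc) > 0:
                r_slope, p_slope = (float(v) for v in stats.pearsonr(pot, sc))
            if np.ptp(pot) > 0 and np.ptp(off) > 0:
                r_off, p_off = (float(v) for v in stats.pearsonr(pot, off))
    return PopulationSummary(
        n_groups=len(results),
        fraction_linear=frac_linear,
        fraction_slope_unchanged=frac_unchanged,
        median_slope_change_pct=median_change,
        offset_mean_pct=offset_mean,
        offset_sd_pct=offset_sd,
        pearson_r_slope=r_slope,
        pearson_p_slope=p_slope,
        pearson_r_offset=r_off,
        pearson_p_offset=p_off,
    )


def results_frame(results: list[TransformResult]) -> pd.DataFrame:
    """Tidy per-group TransformResult table."""
    return pd.DataFrame([r.__dict__ for r in results])
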