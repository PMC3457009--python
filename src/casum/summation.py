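"""Linear-summation fits of cell-group input-output curves.

Two models test whether a cell group sums its electrode inputs
linearly:

* **Model 0** — per group, find the lumped weight vector ``W(k)`` that
  least-squares fits the trial-mean responses to *all* binary patterns:
  ``O_estimated = sum_i I_i * W(k)_i``, minimizing
  ``Error = sum_patterns (O_actual - O_estimated)^2``.
* **Model 1** — use the group's measured single-electrode responses as
  fixed weights: the predicted response to a pattern is the summed
  single-electrode response (SSER), ``sum_{active i} O_i``.  Both axes
  are normalized by the group's mean response over all patterns.

The input-output curve (actual vs. predicted) is then fit by a straight
line *through the origin*, and scatter around the line is scored with
the uncentered statistic

    R^2 = 1 - sum (y - b*x)^2 / sum y^2

(denominator the raw sum of squares of the responses, **not** the
variance around their mean — this deliberately differs from the
textbook centered R^2).  A group is classified linear iff R^2 > 0.75,
strictly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import StimulusPattern, design_matrix, enumerate_patterns, iter_singletons
from .response import ResponseMatrix

logger = logging.getLogger(__name__)

LINEARITY_R2_THRESHOLD = 0.75
ModelName = Literal["model0", "model1"]


@dataclass(frozen=True)
class SingleElectrodeResponses:
    """Per-group mean responses to each electrode stimulated alone.

    Electrodes whose singleton stimulation elicited no detectable
    response are zero-assigned, recorded in ``zero_assigned``.
    """

    group_id: str
    responses: tuple[float, ...]
    zero_assigned: tuple[bool, ...]

    @property
    def n_electrodes(self) -> int:
        return len(self.responses)


@dataclass(frozen=True)
class WeightFit:
    """Model 0 least-squares weights for one group, with the residual error."""

    group_id: str
    weights: tuple[float, ...]
    residual: float  # sum of squared errors over patterns, >= 0


@dataclass(frozen=True)
class IOFitResult:
    """Through-origin regression summary of one group's I-O curve."""

    group_id: str
    model: ModelName
    slope: float
    r2: float
    linear: bool
    slope_ci95: tuple[float, float]
    n_points: int


def apply_detection_floor(values: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Zero out responses at or below the detection floor.

    Mirrors the minimum detectable level of cellular activation in the
    calcium readout: sub-floor ΔF/F is indistinguishable from no spike.
    """
    out = np.asarray(values, dtype=float).copy()
    out[out <= floor] = 0.0
    return out


def single_electrode_responses(
    matrix: ResponseMatrix, detection_floor: float = 0.0
) -> dict[str, SingleElectrodeResponses]:
    """Extract per-group singleton-pattern responses (Model 1 weights)."""
    agg = matrix.aggregate()
    singles = list(iter_singletons(matrix.n_electrodes))
    out: dict[str, SingleElectrodeResponses] = {}
    for gid in matrix.group_ids:
        tbl = agg.loc[gid]
        resp, zeroed = [], []
        for pat in singles:
            if pat.pattern_id not in tbl.index:
                raise ValueError(
                    f"group {gid}: missing single-electrode pattern {pat.bits_string}"
                )
            v = float(tbl.loc[pat.pattern_id, "peak_dff"])
            if v <= detection_floor:
                resp.append(0.0)
                zeroed.append(True)
            else:
                resp.append(v)
                zeroed.append(False)
        out[gid] = SingleElectrodeResponses(
            group_id=gid, responses=tuple(resp), zero_assigned=tuple(zeroed)
        )
    return out


def predict_model1(ser: SingleElectrodeResponses, pattern: StimulusPattern) -> float:
    """Summed single-electrode response (SSER) for one pattern."""
    if pattern.n_electrodes != ser.n_electrodes:
        raise ValueError(
            f"pattern has {pattern.n_electrodes} electrodes, "
            f"responses have {ser.n_electrodes}"
        )
    return float(pattern.as_array() @ np.asarray(ser.responses))


def fit_model0(matrix: ResponseMatrix, detection_floor: float = 0.0) -> dict[str, WeightFit]:
    """Per-group least-squares lumped weights over all patterns.

    Solves the normal equations of ``actual ~ patterns @ W`` on the
    trial-mean responses.  With the full ``2**N - 1`` pattern set the
    design has full column rank; a rank-deficient design (possible only
    for incomplete pattern sets) raises.
    """
    agg = matrix.aggregate()
    pats = matrix.patterns()
    X = design_matrix(pats)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("stimulation pattern set is rank-deficient; cannot fit weights")
    fits: dict[str, WeightFit] = {}
    for gid in matrix.group_ids:
        tbl = agg.loc[gid].reindex([p.pattern_id for p in pats])
        y = apply_detection_floor(tbl["peak_dff"].to_numpy(), detection_floor)
        w, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = float(np.sum((y - X @ w) ** 2))
        fits[gid] = WeightFit(group_id=gid, weights=tuple(float(v) for v in w), residual=resid)
    return fits


@dataclass(frozen=True)
class IOCurve:
    """Included (predicted, actual) points of one group's I-O curve."""

    group_id: str
    model: ModelName
    predicted: np.ndarray
    actual: np.ndarray
    n_excluded: int


def io_curve(
    matrix: ResponseMatrix,
    model: ModelName = "model1",
    detection_floor: float = 0.0,
    normalize_both_axes: bool = True,
) -> dict[str, IOCurve]:
    """Per-group (predicted, actual) response pairs for the chosen model.

    Model 0 predictions are ``patterns @ W(k)`` from :func:`fit_model0`;
    Model 1 predictions are the SSER.  Under Model 1, predicted and
    actual are divided by the group's mean actual response over all
    patterns (set ``normalize_both_axes=False`` to normalize actuals
    only).  Points with predicted == 0 and actual == 0 carry no
    information about the transform and are excluded.  Groups whose mean
    response is zero cannot be normalized and are skipped with a warning.
    """
    agg = matrix.aggregate()
    pats = matrix.patterns()
    X = design_matrix(pats)
    curves: dict[str, IOCurve] = {}
    w_fits = fit_model0(matrix, detection_floor) if model == "model0" else None
    sers = single_electrode_responses(matrix, detection_floor) if model == "model1" else None

    for gid in matrix.group_ids:
        tbl = agg.loc[gid].reindex([p.pattern_id for p in pats])
        actual = apply_detection_floor(tbl["peak_dff"].to_numpy(), detection_floor)
        if model == "model0":
            predicted = X @ np.asarray(w_fits[gid].weights)
        else:
            predicted = X @ np.asarray(sers[gid].responses)
            mean_actual = float(actual.mean())
            if mean_actual <= 0:
                logger.warning("group %s: mean response is 0; skipped under model1", gid)
                continue
            actual = actual / mean_actual
            if normalize_both_axes:
                predicted = predicted / mean_actual
        keep = ~((predicted == 0) & (actual == 0))
        curves[gid] = IOCurve(
            group_id=gid,
            model=model,
            predicted=predicted[keep],
            actual=actual[keep],
            n_excluded=int((~keep).sum()),
        )
    return curves


def origin_slope(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Least-squares slope of ``actual ~ slope * predicted`` through 0."""
    sxx = float(np.sum(predicted**2))
    if sxx == 0:
        raise ValueError("all predicted values are zero; slope undefined")
    return float(np.sum(predicted * actual) / sxx)


def scatter_r2(predicted: np.ndarray, actual: np.ndarray, slope: float) -> float:
    """Uncentered scatter statistic 1 - SS_resid / sum(actual^2)."""
    syy = float(np.sum(actual**2))
    if syy == 0:
        raise ValueError("all actual values are zero; scatter undefined")
    resid = actual - slope * predicted
    return 1.0 - float(np.sum(resid**2)) / syy


def fit_io(
    points: IOCurve | tuple[np.ndarray, np.ndarray],
    group_id: str = "",
    model: ModelName = "model1",
) -> IOFitResult:
    """Fit a through-origin line to an I-O curve and classify linearity.

    The 95% slope CI uses the t distribution with ``n - 1`` degrees of
    freedom and the through-origin slope standard error
    ``sqrt(SS_resid / (n - 1) / sum x^2)``.
    """
    if isinstance(points, IOCurve):
        x, y = points.predicted, points.actual
        group_id, model = points.group_id, points.model
    else:
        x, y = np.asarray(points[0], float), np.asarray(points[1], float)
    n = len(x)
    if n < 3 or not np.any(x > 0):
        raise ValueError(f"group {group_id!r}: need >= 3 included points with predicted > 0")
    slope = origin_slope(x, y)
    r2 = scatter_r2(x, y, slope)
    ss_resid = float(np.sum((y - slope * x) ** 2))
    se = np.sqrt(ss_resid / (n - 1) / np.sum(x**2))
    tcrit = stats.t.ppf(0.975, df=n - 1)
    ci = (slope - tcrit * se, slope + tcrit * se)
    return IOFitResult(
        group_id=group_id,
        model=model,
        slope=slope,
        r2=r2,
        linear=bool(r2 > LINEARITY_R2_THRESHOLD),
        slope_ci95=ci,
        n_points=n,
    )


def analyze_matrix(
    matrix: ResponseMatrix,
    model: ModelName = "model1",
    detection_floor: float = 0.0,
    normalize_both_axes: bool = True,
) -> pd.DataFrame:
    """Fit every group's I-O curve; tidy per-group fit table.

    Columns: group_id, model, slope, r2, linear, ci_lo, ci_hi, n_points.
    Groups with too few usable points are dropped with a warning.
    """
    curves = io_curve(matrix, model, detection_floor, normalize_both_axes)
    rows = []
    for gid, curve in curves.items():
        try:
            fit = fit_io(curve)
        except ValueError as exc:
            logger.warning("group %s: %s", gid, exc)
            continue
        rows.append(
            {
                "group_id": gid,
                "model": fit.model,
                "slope": fit.slope,
                "r2": fit.r2,
                "linear": fit.linear,
                "ci_lo": fit.slope_ci95[0],
                "ci_hi": fit.slope_ci95[1],
                "n_points": fit.n_points,
            }
        )
    if not rows:
        raise ValueError("no group could be fit")
    return pd.DataFrame(rows)


def model1_residual(matrix: ResponseMatrix, detection_floor: float = 0.0) -> dict[str, float]:
    """Model 1's value of the Model 0 objective: SSE of actual vs SSER.

    Model 0 minimizes this same objective, so its residual can never
    exceed this one — the optimality cross-check used in the tests.
    """
    agg = matrix.aggregate()
    pats = matrix.patterns()
    X = design_matrix(pats)
    sers = single_electrode_responses(matrix, detection_floor)
    out = {}
    for gid in matrix.group_ids:
        tbl = agg.loc[gid].reindex([p.pattern_id for p in pats])
        y = apply_detection_floor(tbl["peak_dff"].to_numpy(), detection_floor)
        pred = X @ np.asarray(sers[gid].responses)
        out[gid] = float(np.sum((y - pred) ** 2))
    return out
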