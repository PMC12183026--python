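"""Per-meal glycemic target and prior-glucose features from a CGM trace.

The target is the 2-h incremental area under the curve (iAUC, mmol·min/L)
over a minima-searched baseline: within the 30 min before the (logged)
mealtime the local glucose minimum closest to the meal is taken as the
baseline, and the 2-h window is anchored at that baseline time.  Only the
positive part of the excursion counts; segments crossing the baseline are
split at the interpolated crossing ("cut" convention).

Gap handling: pairs of samples 15-30 min apart are bridged with a single
midpoint sample holding the arithmetic mean; any unfilled gap longer than
30 min inside a computation window excludes the meal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_GAP_MIN = 30.0
BASELINE_SEARCH_MIN = 30.0
IAUC_HORIZON_MIN = 120.0
_EPS = 1e-9


class CoverageError(ValueError):
    """The trace does not cover the requested window."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class GapError(CoverageError):
    """An unfilled gap > 30 min lies inside the computation window."""


def fill_gaps(
    t: np.ndarray, y: np.ndarray, sample_interval: float = 15.0
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Bridge gaps in (sample_interval, 30] min with one midpoint mean sample.

    Longer gaps are left untouched and returned as (t_before, t_after) pairs.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dt = np.diff(t)
    fill = (dt > sample_interval + _EPS) & (dt <= MAX_GAP_MIN + _EPS)
    long_gaps = [(float(t[i]), float(t[i + 1])) for i in np.nonzero(dt > MAX_GAP_MIN + _EPS)[0]]
    if not fill.any():
        return t, y, long_gaps
    idx = np.nonzero(fill)[0]
    t_new = (t[idx] + t[idx + 1]) / 2.0
    y_new = (y[idx] + y[idx + 1]) / 2.0
    t_out = np.insert(t, idx + 1, t_new)
    y_out = np.insert(y, idx + 1, y_new)
    return t_out, y_out, long_gaps


def find_baseline(
    t: np.ndarray,
    y: np.ndarray,
    meal_time: float,
    search_window: float = BASELINE_SEARCH_MIN,
) -> tuple[float, float]:
    """Local pre-meal glucose minimum closest to the meal.

    Searches samples in [meal_time - search_window, meal_time].  A sample
    qualifies when it is <= both in-window neighbours (window edges compared
    one-sided); ties are broken toward the mealtime.  For a monotone window
    this reduces to the window minimum.
    """
    if t.size == 0 or t[0] > meal_time - search_window + _EPS:
        raise CoverageError("no_pre_meal_samples")
    lo = np.searchsorted(t, meal_time - search_window - _EPS, side="left")
    hi = np.searchsorted(t, meal_time + _EPS, side="right")
    tw, yw = t[lo:hi], y[lo:hi]
    if tw.size == 0:
        raise CoverageError("no_pre_meal_samples")
    cand = []
    for i in range(tw.size):
        ok_left = i == 0 or yw[i] <= yw[i - 1] + _EPS
        ok_right = i == tw.size - 1 or yw[i] <= yw[i + 1] + _EPS
        if ok_left and ok_right:
            cand.append(i)
    if not cand:  # strictly non-monotone zig-zag with no local min cannot occur,
        cand = [int(np.argmin(yw))]  # but fall back to the window minimum
    best = max(cand, key=lambda i: tw[i])  # closest to mealtime; ties toward meal
    return float(tw[best]), float(yw[best])


def _window_samples(
    t: np.ndarray, y: np.ndarray, start: float, end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Trace restricted to [start, end] with endpoint interpolation.

    Raises CoverageError / GapError when the window is not covered or an
    unfilled gap > 30 min touches it.
    """
    i0 = np.searchsorted(t, start + _EPS, side="left") - 1
    i1 = np.searchsorted(t, end - _EPS, side="right")
    if i0 < 0 or i1 >= t.size:
        # allow exact-endpoint coverage
        if i0 < 0 and t.size and abs(t[0] - start) <= _EPS:
            i0 = 0
        if i1 >= t.size and t.size and abs(t[-1] - end) <= _EPS:
            i1 = t.size - 1
        if i0 < 0 or i1 >= t.size:
            raise CoverageError("insufficient_coverage")
    seg_t = t[i0 : i1 + 1]
    seg_y = y[i0 : i1 + 1]
    if np.any(np.diff(seg_t) > MAX_GAP_MIN + _EPS):
        raise GapError("gap_gt_30min_in_window")
    ts = np.clip(seg_t, start, end)
    ys = seg_y.copy()
    ys[0] = np.interp(start, seg_t, seg_y)
    ys[-1] = np.interp(end, seg_t, seg_y)
    ts[0], ts[-1] = start, end
    keep = np.concatenate(([True], np.diff(ts) > 0))
    return ts[keep], ys[keep]


def positive_trapezoid(ts: np.ndarray, zs: np.ndarray) -> float:
    """Integral of max(z, 0) for the piecewise-linear curve (ts, zs)."""
    area = 0.0
    for a in range(ts.size - 1):
        za, zb = zs[a], zs[a + 1]
        dt = ts[a + 1] - ts[a]
        if za >= 0 and zb >= 0:
            area += 0.5 * (za + zb) * dt
        elif za <= 0 and zb <= 0:
            continue
        else:  # baseline crossing: keep the positive triangle only
            tc = dt * za / (za - zb)
            if za > 0:
                area += 0.5 * za * tc
            else:
                area += 0.5 * zb * (dt - tc)
    return float(area)


def compute_iauc(
    t: np.ndarray,
    y: np.ndarray,
    start_time: float,
    baseline_value: float,
    horizon: float = IAUC_HORIZON_MIN,
) -> float:
    """Trapezoidal iAUC of max(0, glucose - baseline) over [start, start+horizon]."""
    ts, ys = _window_samples(t, y, start_time, start_time + horizon)
    return positive_trapezoid(ts, ys - baseline_value)


def glucose_trend(
    t: np.ndarray, y: np.ndarray, meal_time: float, interval_h: float
) -> float | None:
    """Least-squares slope (mmol/L per hour) over the pre-meal interval."""
    lo = np.searchsorted(t, meal_time - interval_h * 60.0 - _EPS, side="left")
    hi = np.searchsorted(t, meal_time + _EPS, side="right")
    tw, yw = t[lo:hi], y[lo:hi]
    if tw.size < 2:
        return None
    x = (tw - tw.mean()) / 60.0
    return float(np.dot(x, yw - yw.mean()) / np.dot(x, x))


def past_iauc(
    t: np.ndarray, y: np.ndarray, meal_time: float, interval_h: float
) -> float | None:
    """iAUC over the pre-meal interval, baseline = window minimum glucose."""
    start = meal_time - interval_h * 60.0
    lo = np.searchsorted(t, start - _EPS, side="left")
    hi = np.searchsorted(t, meal_time + _EPS, side="right")
    if hi - lo < 2:
        return None
    baseline = float(np.min(y[lo:hi]))
    try:
        return compute_iauc(t, y, start, baseline, horizon=interval_h * 60.0)
    except CoverageError:
        return None


def glucose_at(t: np.ndarray, y: np.ndarray, when: float) -> float | None:
    """Linearly interpolated glucose at a time, None across a >30-min gap."""
    i = np.searchsorted(t, when, side="right")
    if i == 0 or i >= t.size:
        if t.size and abs(t[min(i, t.size - 1)] - when) <= _EPS:
            return float(y[min(i, t.size - 1)])
        if i > 0 and abs(t[i - 1] - when) <= _EPS:
            return float(y[i - 1])
        return None
    if t[i] - t[i - 1] > MAX_GAP_MIN + _EPS:
        return None
    return float(np.interp(when, t, y))


@dataclass
class PPGRResult:
    baseline_time: float | None
    baseline_value: float | None
    iauc_2h: float | None
    valid: bool
    exclusion_reason: str | None = None


TREND_INTERVALS_H = (1, 2, 4)


def ppgr_for_meal(t: np.ndarray, y: np.ndarray, meal_time: float) -> tuple[PPGRResult, dict]:
    """Target + glucose feature map for one meal on a gap-filled trace."""
    feats: dict[str, float | None] = {}
    try:
        b_time, b_val = find_baseline(t, y, meal_time)
        iauc = compute_iauc(t, y, b_time, b_val)
        res = PPGRResult(b_time, b_val, iauc, True)
    except CoverageError as err:
        res = PPGRResult(None, None, None, False, err.reason)
        b_val = None
    feats["glucose_at_meal"] = glucose_at(t, y, meal_time)
    feats["baseline_value"] = b_val
    for h in TREND_INTERVALS_H:
        feats[f"trend_{h}h"] = glucose_trend(t, y, meal_time, h)
        feats[f"past_iauc_{h}h"] = past_iauc(t, y, meal_time, h)
    return res, feats


def ppgr_for_meals(
    t: np.ndarray,
    y: np.ndarray,
    meal_times: np.ndarray,
    sample_interval: float = 15.0,
    prefilled: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vector version over one participant's meals.

    Returns (ppgr table, glucose-feature table), one row per meal, indexed
    like ``meal_times``.  Exclusions are data (valid=False + reason), not
    errors.
    """
    if not prefilled:
        t, y, _ = fill_gaps(t, y, sample_interval)
    pp_rows, gf_rows = [], []
    for mt in np.asarray(meal_times, dtype=float):
        res, feats = ppgr_for_meal(t, y, mt)
        pp_rows.append(
            {
                "meal_time": mt,
                "baseline_time": res.baseline_time,
                "baseline_value": res.baseline_value,
                "iauc_2h": res.iauc_2h,
                "valid": res.valid,
                "exclusion_reason": res.exclusion_reason,
            }
        )
        gf_rows.append({"meal_time": mt, **feats})
    return pd.DataFrame(pp_rows), pd.DataFrame(gf_rows)
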