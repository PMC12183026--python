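"""Independent oracle implementations used only by the test suite.

Each oracle deliberately takes a different computational route from the
package (dense-grid resampling, naive Python loops, closed forms) so that
agreement is evidence of correctness rather than shared code.
"""

from __future__ import annotations

import numpy as np

MGDL_PER_MMOLL = 18.016


def dense_grid_iauc(
    t: np.ndarray, y: np.ndarray, start: float, baseline: float, horizon: float = 120.0
) -> float:
    """Dense-grid trapezoid of max(0, interp(t) - baseline) over the window.

    The grid is the union of a fine uniform grid, the sample times and the
    independently located baseline crossings, which makes the trapezoid
    exact for the piecewise-linear interpolant.
    """
    end = start + horizon
    pts = [start, end]
    pts += [float(tt) for tt in t if start < tt < end]
    # locate crossings independently per bracketing segment
    for i in range(len(t) - 1):
        a, b = t[i], t[i + 1]
        if b <= start or a >= end:
            continue
        za, zb = y[i] - baseline, y[i + 1] - baseline
        if za * zb < 0:
            tc = a + (b - a) * za / (za - zb)
            if start < tc < end:
                pts.append(float(tc))
    grid = np.union1d(np.linspace(start, end, 2001), np.array(sorted(pts)))
    vals = np.interp(grid, t, y) - baseline
    return float(np.trapezoid(np.clip(vals, 0.0, None), grid))


def naive_sd(y) -> float:
    n = len(y)
    m = sum(y) / n
    return (sum((v - m) ** 2 for v in y) / (n - 1)) ** 0.5


def naive_mage(y) -> float:
    y = list(y)
    if len(y) < 2:
        return 0.0
    sd = naive_sd(y)
    if sd == 0:
        return 0.0
    # walk the series recording direction changes
    tps = [0]
    direction = 0
    for i in range(1, len(y)):
        d = y[i] - y[i - 1]
        if d == 0:
            continue
        s = 1 if d > 0 else -1
        if direction != 0 and s != direction:
            tps.append(i - 1)
        direction = s
    tps.append(len(y) - 1)
    tps = sorted(set(tps))
    amps = [abs(y[tps[k + 1]] - y[tps[k]]) for k in range(len(tps) - 1)]
    qual = [a for a in amps if a > sd]
    return sum(qual) / len(qual) if qual else 0.0


def naive_conga(t, y, lag_h, tol=1.0):
    lag = lag_h * 60.0
    diffs = []
    for i in range(len(t)):
        target = t[i] - lag
        best, bd = None, None
        for j in range(len(t)):
            d = abs(t[j] - target)
            if bd is None or d < bd:
                best, bd = j, d
        if bd is not None and bd <= tol:
            diffs.append(y[i] - y[best])
    if len(diffs) < 2:
        return None
    return naive_sd(diffs)


def _risk_fn(g_mmol):
    f = 1.509 * ((np.log(g_mmol * MGDL_PER_MMOLL)) ** 1.084 - 5.381)
    return f


def naive_lbgi(y):
    total = 0.0
    for v in y:
        f = _risk_fn(v)
        if f < 0:
            total += 10 * f * f
    return total / len(y)


def naive_hbgi(y):
    total = 0.0
    for v in y:
        f = _risk_fn(v)
        if f > 0:
            total += 10 * f * f
    return total / len(y)


def naive_adrr(t, y):
    if len(t) < 2 or t[-1] - t[0] < 1440:
        return None
    byday: dict[int, list[float]] = {}
    for tt, v in zip(t, y):
        byday.setdefault(int(tt // 1440), []).append(v)
    ranges = []
    for vals in byday.values():
        lo = max((10 * _risk_fn(v) ** 2 for v in vals if _risk_fn(v) < 0), default=0.0)
        hi = max((10 * _risk_fn(v) ** 2 for v in vals if _risk_fn(v) > 0), default=0.0)
        ranges.append(lo + hi)
    return sum(ranges) / len(ranges)


def naive_gmi(y):
    return 3.31 + 0.02392 * (sum(y) / len(y)) * MGDL_PER_MMOLL


def naive_time_in_range(y, lo=3.9, hi=10.0):
    return sum(1 for v in y if lo <= v <= hi) / len(y)


def greedy_merge_clusters(times: list[float], window: float = 30.0) -> list[list[int]]:
    """Brute-force enumeration of the greedy cluster rule on sorted times."""
    clusters: list[list[int]] = []
    for i, tt in enumerate(times):
        if clusters and tt - times[clusters[-1][0]] <= window:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    return clusters


def stump_shap(x: np.ndarray, threshold: float, left_value: float, right_value: float,
               left_weight: float, right_weight: float) -> tuple[np.ndarray, float]:
    """Hand Shapley values for a single depth-1 tree on one feature.

    With one feature the Shapley value of a sample is its leaf value minus
    the cover-weighted expectation over leaves.
    """
    total = left_weight + right_weight
    base = (left_weight * left_value + right_weight * right_value) / total
    leaf = np.where(x < threshold, left_value, right_value)
    return leaf - base, base
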