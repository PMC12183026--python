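"""Cumulative day-level glycemic-variability metrics.

Each kernel is a pure function of one participant's sample sequence
(t minutes, glucose mmol/L).  The cumulative table gives, for every study
day from day 2 onward, each metric computed over all samples strictly
before that day's midnight — i.e. only past information.

Conventions (documented where the literature is not unique):

* MAGE — threshold 1x sample SD; turning points detected on the raw
  series (series endpoints included); amplitudes between consecutive
  turning points; excursions in both directions averaged; no qualifying
  excursion -> 0.
* CONGA(lag) — SD (ddof=1) of differences between samples exactly ``lag``
  apart, matched on-grid with a +-1 min tolerance.
* LBGI/HBGI — Kovatchev risk transform on mg/dL (mmol/L x 18.016):
  f(g) = 1.509 ((ln g)^1.084 - 5.381), risk = 10 f^2 split by sign.
* ADRR — per calendar day max low risk + max high risk, averaged over
  days; requires at least one full day of span.
* GMI — 3.31 + 0.02392 x mean glucose in mg/dL (%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MGDL_PER_MMOLL = 18.016
MINUTES_PER_DAY = 1440


def mean_glucose(y: np.ndarray) -> float:
    return float(np.mean(y))


def sd_glucose(y: np.ndarray) -> float:
    return float(np.std(y, ddof=1))


def cv_glucose(y: np.ndarray) -> float:
    return sd_glucose(y) / mean_glucose(y)


def time_in_range(y: np.ndarray, lo: float = 3.9, hi: float = 10.0) -> float:
    return float(np.mean((y >= lo) & (y <= hi)))


def gmi(y: np.ndarray) -> float:
    return 3.31 + 0.02392 * mean_glucose(y) * MGDL_PER_MMOLL


def _turning_points(y: np.ndarray) -> np.ndarray:
    """Indices of series endpoints plus interior direction changes."""
    dy = np.diff(y)
    nz = np.nonzero(dy)[0]
    if nz.size == 0:
        return np.array([0, y.size - 1]) if y.size > 1 else np.array([0])
    tps = [0]
    prev_sign = np.sign(dy[nz[0]])
    for k in nz[1:]:
        s = np.sign(dy[k])
        if s != prev_sign:
            tps.append(k)  # index where the previous run ended
            prev_sign = s
    tps.append(y.size - 1)
    return np.unique(tps)


def mage(y: np.ndarray) -> float:
    """Mean amplitude of glycemic excursions exceeding 1 sample SD."""
    if y.size < 2:
        return 0.0
    sd = sd_glucose(y)
    if sd == 0:
        return 0.0
    tps = _turning_points(y)
    amps = np.abs(np.diff(y[tps]))
    qual = amps[amps > sd]
    return float(qual.mean()) if qual.size else 0.0


def conga(t: np.ndarray, y: np.ndarray, lag_h: float, tol_min: float = 1.0) -> float | None:
    """SD of glucose differences between samples exactly ``lag_h`` apart."""
    lag = lag_h * 60.0
    targets = t - lag
    j = np.searchsorted(t, targets)
    j = np.clip(j, 0, t.size - 1)
    jm = np.clip(j - 1, 0, t.size - 1)
    pick = np.where(np.abs(t[j] - targets) <= np.abs(t[jm] - targets), j, jm)
    ok = np.abs(t[pick] - targets) <= tol_min
    d = y[ok] - y[pick[ok]]
    if d.size < 2:
        return None
    return float(np.std(d, ddof=1))


def _risk(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = y * MGDL_PER_MMOLL
    f = 1.509 * (np.log(g) ** 1.084 - 5.381)
    r = 10.0 * f**2
    return np.where(f < 0, r, 0.0), np.where(f > 0, r, 0.0)


def lbgi(y: np.ndarray) -> float:
    return float(np.mean(_risk(y)[0]))


def hbgi(y: np.ndarray) -> float:
    return float(np.mean(_risk(y)[1]))


def adrr(t: np.ndarray, y: np.ndarray) -> float | None:
    """Average daily risk range; None with less than one full day of span."""
    if t.size < 2 or t[-1] - t[0] < MINUTES_PER_DAY:
        return None
    rl, rh = _risk(y)
    days = np.floor(t / MINUTES_PER_DAY).astype(int)
    out = []
    for d in np.unique(days):
        m = days == d
        out.append(rl[m].max() + rh[m].max())
    return float(np.mean(out))


#: Registry of sequence-order-free kernels (value functions of y only).
SHUFFLE_INVARIANT_KERNELS = {
    "mean_glucose": mean_glucose,
    "sd": sd_glucose,
    "cv": cv_glucose,
    "time_in_range_3.9_10": time_in_range,
    "gmi": gmi,
    "lbgi": lbgi,
    "hbgi": hbgi,
}


def metrics_row(t: np.ndarray, y: np.ndarray) -> dict[str, float | None]:
    """All metrics for one sample prefix (>= 2 samples)."""
    row: dict[str, float | None] = {k: fn(y) for k, fn in SHUFFLE_INVARIANT_KERNELS.items()}
    row["mage"] = mage(y)
    for h in (1, 2, 4):
        row[f"conga_{h}h"] = conga(t, y, h)
    row["adrr"] = adrr(t, y)
    return row


def cumulative_metrics(t: np.ndarray, y: np.ndarray, day_index: int) -> dict | None:
    """Metrics over all samples strictly before day ``day_index`` (1-based).

    Day 1 starts at the midnight of the first sample; day_index must be
    >= 2.  Returns None when fewer than 2 prior samples exist.
    """
    if day_index < 2:
        raise ValueError("cumulative metrics exist from day 2 onward")
    day0 = np.floor(t[0] / MINUTES_PER_DAY)
    cutoff = (day0 + day_index - 1) * MINUTES_PER_DAY
    m = t < cutoff
    if m.sum() < 2:
        return None
    return metrics_row(t[m], y[m])


def cumulative_metrics_table(
    t: np.ndarray, y: np.ndarray, participant_id: str, n_days: int
) -> pd.DataFrame:
    """One row per study day 2..n_days, keyed by (participant, day index)."""
    rows = []
    day0 = int(np.floor(t[0] / MINUTES_PER_DAY)) if t.size else 0
    for d in range(2, n_days + 1):
        row = cumulative_metrics(t, y, d)
        if row is None:
            continue
        rows.append({"participant_id": participant_id, "day_index": d, "day": day0 + d - 1, **row})
    return pd.DataFrame(rows)
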