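"""Dietary feature engineering: trimming, merging, timing, Dc and Dt groups.

Dc (compositional) — per-meal nutrient content: macronutrients, fiber,
energy, eaten quantity, the six food-class gram columns, and the
fat/carb and protein/carb ratios (zero-carb meals get ratio 0).

Dt (temporal) — meal timing class, time since last meal, and nutrient
sums over the 1, 2, 3, 6 and 12 h windows preceding the meal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import FOOD_CLASSES

log = logging.getLogger(__name__)

MERGE_WINDOW_MIN = 30.0
TRIM_MARGIN_MIN = 12 * 60.0
TEMPORAL_WINDOWS_H = (1, 2, 3, 6, 12)
NO_PRIOR_MEAL_HORIZON_H = 12.0

_SUM_COLS = [
    "carbs_g", "fat_g", "protein_g", "fiber_g", "energy_kcal", "eaten_quantity_g",
    *FOOD_CLASSES,
]


def classify_meal_timing(timestamp) -> str:
    """breakfast before 10:00, lunch in [10:00, 16:00), dinner from 16:00."""
    if hasattr(timestamp, "hour"):
        hour = timestamp.hour + timestamp.minute / 60.0
    else:  # minutes on the study axis
        hour = (float(timestamp) / 60.0) % 24.0
    if hour < 10.0:
        return "breakfast"
    if hour < 16.0:
        return "lunch"
    return "dinner"


def trim_meals(meals: pd.DataFrame, trace_start_min: float, trace_end_min: float) -> pd.DataFrame:
    """Keep meals with >= 12 h of glucose on both sides (boundaries inclusive)."""
    if trace_end_min - trace_start_min < 24 * 60.0:
        log.warning("trace shorter than 24 h: all %d meals dropped", len(meals))
        return meals.iloc[0:0].copy()
    lo = trace_start_min + TRIM_MARGIN_MIN
    hi = trace_end_min - TRIM_MARGIN_MIN
    kept = meals[(meals["t_min"] >= lo) & (meals["t_min"] <= hi)].copy()
    if len(kept) < len(meals):
        log.info("trim_meals dropped %d of %d meals", len(meals) - len(kept), len(meals))
    return kept


def merge_meals(meals: pd.DataFrame, window: float = MERGE_WINDOW_MIN) -> pd.DataFrame:
    """Merge same-participant meals within ``window`` min of a cluster start.

    Greedy left-to-right: a meal joins the open cluster when it is within
    ``window`` minutes of the cluster's FIRST timestamp; nutrient, energy
    and food-class columns are summed and the merged meal keeps the
    earliest timestamp.  Idempotent by construction.
    """
    out = []
    for pid, grp in meals.groupby("participant_id", sort=True):
        grp = grp.sort_values("t_min", kind="stable")
        cluster: list[pd.Series] = []
        for _, row in grp.iterrows():
            if cluster and row["t_min"] - cluster[0]["t_min"] <= window:
                cluster.append(row)
            else:
                if cluster:
                    out.append(_collapse(cluster))
                cluster = [row]
        if cluster:
            out.append(_collapse(cluster))
    if not out:
        return meals.iloc[0:0].copy()
    return pd.DataFrame(out).reset_index(drop=True)


def _collapse(cluster: list[pd.Series]) -> pd.Series:
    first = cluster[0].copy()
    if len(cluster) == 1:
        return first
    block = pd.DataFrame(cluster)
    for col in _SUM_COLS:
        if col in block:
            first[col] = block[col].sum()
    labels = block["standardized_label"].dropna() if "standardized_label" in block else []
    if len(labels):
        first["standardized_label"] = labels.iloc[0]
    return first


def compositional_features(meal: pd.Series) -> dict[str, float]:
    """Dc map for one (merged) meal."""
    carbs = float(meal["carbs_g"])
    out = {col: float(meal[col]) for col in _SUM_COLS}
    out["fat_carb_ratio"] = float(meal["fat_g"]) / carbs if carbs > 0 else 0.0
    out["protein_carb_ratio"] = float(meal["protein_g"]) / carbs if carbs > 0 else 0.0
    return out


def temporal_features(meals: pd.DataFrame) -> pd.DataFrame:
    """Dt map for every meal of one participant (meals sorted by t_min).

    Window sums cover t_meal - w <= t < t_meal (the meal itself excluded).
    ``time_since_last_meal_min`` is NaN with has_prior_meal = 0 when no
    meal precedes within the 12-h horizon.
    """
    t = meals["t_min"].to_numpy(dtype=float)
    nutr = meals[["carbs_g", "fat_g", "protein_g", "energy_kcal"]].to_numpy(dtype=float)
    rows = []
    for i in range(len(meals)):
        row: dict[str, float] = {}
        timing = classify_meal_timing(t[i])
        row["meal_timing"] = timing
        for lab in ("breakfast", "lunch", "dinner"):
            row[f"is_{lab}"] = float(timing == lab)
        prior = np.nonzero((t < t[i]) & (t >= t[i] - NO_PRIOR_MEAL_HORIZON_H * 60.0))[0]
        if prior.size:
            row["time_since_last_meal_min"] = float(t[i] - t[prior[-1]])
            row["has_prior_meal"] = 1.0
        else:
            row["time_since_last_meal_min"] = np.nan
            row["has_prior_meal"] = 0.0
        for w in TEMPORAL_WINDOWS_H:
            m = (t >= t[i] - w * 60.0) & (t < t[i])
            sums = nutr[m].sum(axis=0) if m.any() else np.zeros(4)
            row[f"carbs_past_{w}h_g"] = sums[0]
            row[f"fat_past_{w}h_g"] = sums[1]
            row[f"protein_past_{w}h_g"] = sums[2]
            row[f"energy_past_{w}h_kcal"] = sums[3]
        rows.append(row)
    return pd.DataFrame(rows, index=meals.index)


def diet_feature_table(meals: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dc + Dt features for merged, trimmed meals of the whole cohort.

    Returns the feature frame (indexed like ``meals``) and the mapping
    {"Dc": [...], "Dt": [...]} of feature-column names.
    """
    dc = pd.DataFrame(
        [compositional_features(row) for _, row in meals.iterrows()], index=meals.index
    )
    dt_parts = []
    for _, grp in meals.groupby("participant_id", sort=True):
        dt_parts.append(temporal_features(grp.sort_values("t_min", kind="stable")))
    dt = pd.concat(dt_parts).loc[meals.index] if dt_parts else pd.DataFrame(index=meals.index)
    dc_cols = list(dc.columns)
    dt_cols = [c for c in dt.columns if c != "meal_timing"]
    feats = pd.concat([dc, dt], axis=1)
    return feats, {"Dc": dc_cols, "Dt": dt_cols}
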