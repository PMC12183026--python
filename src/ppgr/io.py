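"""Shared domain-table schemas, validated read/write, and the feature table.

All tables are plain CSV (optionally parquet for intermediates) with
ISO-8601 UTC timestamps.  Window arithmetic elsewhere runs on a
timezone-free minute axis derived here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FEATURE_GROUPS, FOOD_CLASSES
from .simulate import CohortBundle

log = logging.getLogger(__name__)

GLUCOSE_MIN, GLUCOSE_MAX = 2.0, 30.0

TRACE_COLS = ["participant_id", "timestamp", "glucose_mmol_l"]
MEAL_COLS = [
    "participant_id", "timestamp", "carbs_g", "fat_g", "protein_g", "fiber_g",
    "energy_kcal", "eaten_quantity_g", *FOOD_CLASSES, "standardized_label",
]
ACTIVITY_COLS = ["participant_id", "kind", "start", "end"]


class SchemaError(ValueError):
    """A table is missing required columns or violates row constraints."""


def to_minutes(ts: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """UTC timestamps -> float minutes since the Unix epoch."""
    vals = pd.DatetimeIndex(ts)
    if vals.tz is None:
        vals = vals.tz_localize("UTC")
    return vals.tz_convert("UTC").asi8 / 60e9


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def _parse_timestamps(df: pd.DataFrame, col: str, table: str) -> pd.DataFrame:
    parsed = pd.to_datetime(df[col], errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & df[col].notna()
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # +header +0-base
        raise SchemaError(f"{table}: unparseable timestamp(s) at line(s) {lines[:10]}")
    df = df.copy()
    df[col] = parsed
    return df


def validate_traces(traces: pd.DataFrame) -> pd.DataFrame:
    _require_columns(traces, TRACE_COLS, "traces")
    dup = traces.duplicated(["participant_id", "timestamp"])
    if dup.any():
        raise SchemaError(
            f"traces: duplicate (participant, timestamp) rows at index {list(traces.index[dup][:10])}"
        )
    bad = ~traces["glucose_mmol_l"].between(GLUCOSE_MIN, GLUCOSE_MAX)
    if bad.any():
        rows = traces.loc[bad, TRACE_COLS].head(10)
        raise SchemaError(f"traces: glucose outside [{GLUCOSE_MIN}, {GLUCOSE_MAX}] mmol/L:\n{rows}")
    return traces.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)


def validate_meals(meals: pd.DataFrame) -> pd.DataFrame:
    _require_columns(meals, MEAL_COLS, "meals")
    gram_cols = [c for c in MEAL_COLS if c.endswith("_g") or c in FOOD_CLASSES] + ["energy_kcal"]
    neg = (meals[gram_cols] < 0).any(axis=1)
    if neg.any():
        raise SchemaError(f"meals: negative grams/energy at index {list(meals.index[neg][:10])}")
    return meals.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)


def write_cohort(bundle: CohortBundle, out_dir: str | Path, fmt: str = "csv") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "traces": bundle.traces,
        "meals": bundle.meals,
        "personal": bundle.personal,
        "microbiome": bundle.microbiome,
        "activity": bundle.activity,
        "truth": bundle.truth_meals,
        "truth_participants": bundle.truth_participants,
    }
    paths = {}
    for name, df in tables.items():
        if fmt == "parquet":
            p = out / f"{name}.parquet"
            df.to_parquet(p, index=False)
        else:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")
        paths[name] = p
    return paths


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        alt = path.with_suffix(".parquet" if path.suffix == ".csv" else ".csv")
        if alt.exists():
            path = alt
        else:
            raise FileNotFoundError(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def read_cohort(in_dir: str | Path, config=None) -> CohortBundle:
    """Read and validate a cohort directory written by :func:`write_cohort`."""
    d = Path(in_dir)
    traces = _parse_timestamps(_read_table(d / "traces.csv"), "timestamp", "traces")
    traces = validate_traces(traces)
    meals = _parse_timestamps(_read_table(d / "meals.csv"), "timestamp", "meals")
    meals = validate_meals(meals)
    personal = _read_table(d / "personal.csv")
    microbiome = _read_table(d / "microbiome.csv")
    activity = _read_table(d / "activity.csv")
    if len(activity):
        _require_columns(activity, ACTIVITY_COLS, "activity")
        activity = _parse_timestamps(activity, "start", "activity")
        activity = _parse_timestamps(activity, "end", "activity")
    truth_path = d / "truth.csv"
    truth = (
        _parse_timestamps(_read_table(truth_path), "timestamp", "truth")
        if truth_path.exists() or truth_path.with_suffix(".parquet").exists()
        else pd.DataFrame(columns=["participant_id", "timestamp", "true_iauc"])
    )
    tp_path = d / "truth_participants.csv"
    truth_p = (
        _read_table(tp_path)
        if tp_path.exists() or tp_path.with_suffix(".parquet").exists()
        else pd.DataFrame(columns=["participant_id", "sensitivity", "baseline_level"])
    )
    for name, df in [("traces", traces), ("meals", meals)]:
        log.info("read %s: %d rows", name, len(df))
    from .config import SimulationConfig

    return CohortBundle(
        traces=traces, meals=meals, personal=personal, microbiome=microbiome,
        activity=activity, truth_meals=truth, truth_participants=truth_p,
        config=config or SimulationConfig(),
    )


# ---------------------------------------------------------------------------
# Feature table


@dataclass
class FeatureTable:
    """One modeling row per valid meal, with per-group missingness mask.

    ``df`` holds meta columns (participant_id, timestamp, meal_timing,
    standardized_label), the target ``target_iauc`` and every feature
    column; ``groups`` maps each feature-group label to its columns;
    ``mask`` is True where a group is missing for a row.
    """

    df: pd.DataFrame
    groups: dict[str, list[str]]
    mask: pd.DataFrame = field(default_factory=pd.DataFrame)

    def combo_rows(self, combo: list[str] | tuple[str, ...]) -> pd.DataFrame:
        """Rows complete for every group in the combo."""
        keep = ~self.mask[list(combo)].any(axis=1)
        return self.df[keep]

    def combo_columns(self, combo) -> list[str]:
        cols: list[str] = []
        for g in combo:
            cols.extend(self.groups[g])
        return cols

    def combo_counts(self, combos: list[tuple[str, ...]]) -> pd.Series:
        return pd.Series({"+".join(c): len(self.combo_rows(c)) for c in combos})


def _group_missing(df: pd.DataFrame, cols: list[str]) -> pd.Series:
    """Row-wise missingness for one group.

    ``time_since_last_meal_min`` is a sentinel (no prior meal), not missing
    data, when ``has_prior_meal`` is 0 — such rows stay group-complete.
    """
    check = [c for c in cols if c != "time_since_last_meal_min"]
    miss = df[check].isna().any(axis=1) if check else pd.Series(False, index=df.index)
    if "time_since_last_meal_min" in cols and "has_prior_meal" in df.columns:
        tsl_missing = df["time_since_last_meal_min"].isna() & (df["has_prior_meal"] != 0)
        miss = miss | tsl_missing
    return miss


def build_feature_table(
    meals: pd.DataFrame,
    per_meal: dict[str, pd.DataFrame],
    per_participant: dict[str, pd.DataFrame] | None = None,
) -> FeatureTable:
    """Left-join feature groups onto valid meals and build the mask.

    ``meals`` must carry participant_id, timestamp, target_iauc and any
    meta columns; ``per_meal`` frames are aligned on the meals index;
    ``per_participant`` frames are keyed by participant_id.
    """
    if meals.duplicated(["participant_id", "timestamp"]).any():
        raise SchemaError("duplicate meal keys in feature assembly")
    df = meals.copy()
    groups: dict[str, list[str]] = {}
    for g, frame in per_meal.items():
        cols = list(frame.columns)
        groups[g] = cols
        df = df.join(frame, how="left")
    for g, frame in (per_participant or {}).items():
        cols = [c for c in frame.columns if c != "participant_id"]
        groups[g] = cols
        df = df.merge(frame, on="participant_id", how="left")
    df = df.reset_index(drop=True)
    mask = pd.DataFrame(
        {g: _group_missing(df, cols) for g, cols in groups.items()}, index=df.index
    )
    for g in FEATURE_GROUPS:
        if g not in mask.columns:
            mask[g] = True  # group not supplied at all
            groups.setdefault(g, [])
    counts = {g: int((~mask[g]).sum()) for g in mask.columns}
    log.info("feature table: %d rows; complete per group: %s", len(df), counts)
    return FeatureTable(df=df, groups=groups, mask=mask)
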