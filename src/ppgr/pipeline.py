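"""End-to-end orchestration: simulate -> features -> models -> reports.

``cohort_feature_table`` is the single assembly path from a cohort bundle
to the per-meal modeling table; every analysis script, test and the
acceptance harness goes through it.  ``run_pipeline`` adds file outputs,
a deterministic manifest (config hash, derived stage seeds, row-count
accounting) and stage skipping for unchanged configs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, SimulationConfig
from .diet import diet_feature_table, merge_meals, trim_meals
from .glycemic import fill_gaps, ppgr_for_meals
from .interpret import attribute, robustness_surface
from .io import CohortBundle, FeatureTable, build_feature_table, read_cohort, write_cohort
from .metrics import MINUTES_PER_DAY, cumulative_metrics_table
from .modeling import (
    DEFAULT_COMBOS,
    ablation,
    macronutrient_ols,
    train_and_evaluate,
    variance_report,
)
from .simulate import simulate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "features", "train", "ablate", "ols", "variance", "explain", "robustness")


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed derivation (stages independently reproducible)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31))


def _participant_arrays(traces: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    from .io import to_minutes

    t_all = to_minutes(traces["timestamp"])
    out = {}
    for pid, idx in traces.groupby("participant_id", sort=True).groups.items():
        loc = traces.index.get_indexer(idx)
        order = np.argsort(t_all[loc], kind="stable")
        out[pid] = (t_all[loc][order], traces["glucose_mmol_l"].to_numpy()[loc][order])
    return out


def _activity_features(meals: pd.DataFrame, activity: pd.DataFrame) -> pd.DataFrame:
    """Per-meal sleep/activity features (NaN for uncovered participants)."""
    from .io import to_minutes

    cols = ["sleep_duration_min", "min_since_wake", "activity_past_24h_min", "activity_count_24h"]
    out = pd.DataFrame(np.nan, index=meals.index, columns=cols)
    if not len(activity):
        return out
    act = activity.copy()
    act["start_min"] = to_minutes(act["start"])
    act["end_min"] = to_minutes(act["end"])
    for pid, grp in meals.groupby("participant_id", sort=True):
        ev = act[act["participant_id"] == pid]
        if not len(ev):
            continue
        sleep = ev[ev["kind"] == "sleep"].sort_values("end_min")
        moves = ev[ev["kind"] == "activity"]
        for i, row in grp.iterrows():
            t = row["t_min"]
            past = sleep[(sleep["end_min"] <= t) & (sleep["end_min"] >= t - MINUTES_PER_DAY)]
            if len(past):
                last = past.iloc[-1]
                out.loc[i, "sleep_duration_min"] = last["end_min"] - last["start_min"]
                out.loc[i, "min_since_wake"] = t - last["end_min"]
            recent = moves[(moves["end_min"] <= t) & (moves["end_min"] >= t - MINUTES_PER_DAY)]
            out.loc[i, "activity_past_24h_min"] = (
                (recent["end_min"] - recent["start_min"]).sum() if len(recent) else 0.0
            )
            out.loc[i, "activity_count_24h"] = float(len(recent))
    return out


def cohort_feature_table(
    bundle: CohortBundle, metrics_in_g: bool = True
) -> tuple[FeatureTable, dict[str, int]]:
    """Assemble the per-meal modeling table from a cohort bundle.

    Returns the feature table plus the row-count accounting chain
    (logged -> trimmed -> merged -> ppgr-valid).
    """
    from .io import to_minutes

    traces_by_pid = _participant_arrays(bundle.traces)
    meals = bundle.meals.copy()
    meals["t_min"] = to_minutes(meals["timestamp"])
    counts = {"meals_logged": len(meals)}

    trimmed = []
    for pid, grp in meals.groupby("participant_id", sort=True):
        if pid not in traces_by_pid:
            continue
        t, _ = traces_by_pid[pid]
        trimmed.append(trim_meals(grp, t[0], t[-1]))
    meals = pd.concat(trimmed, ignore_index=True) if trimmed else meals.iloc[0:0]
    counts["meals_trimmed"] = len(meals)

    meals = merge_meals(meals)
    counts["meals_merged"] = len(meals)

    diet_feats, diet_groups = diet_feature_table(meals)
    meals["meal_timing"] = diet_feats["meal_timing"]
    diet_feats = diet_feats.drop(columns=["meal_timing"])

    # glycemic targets + G features per participant
    pp_parts, gf_parts, metric_parts = [], [], []
    interval = bundle.config.sample_interval if bundle.config else 15.0
    for pid, grp in meals.groupby("participant_id", sort=True):
        t, y = traces_by_pid[pid]
        tf, yf, _ = fill_gaps(t, y, interval)
        pp, gf = ppgr_for_meals(tf, yf, grp["t_min"].to_numpy(), prefilled=True)
        pp.index = grp.index
        gf.index = grp.index
        pp_parts.append(pp)
        gf_parts.append(gf.drop(columns=["meal_time"]))
        if metrics_in_g:
            n_days = int(np.ceil((t[-1] - t[0]) / MINUTES_PER_DAY))
            metric_parts.append(cumulative_metrics_table(tf, yf, pid, n_days))
    ppgr = pd.concat(pp_parts).loc[meals.index]
    gfeat = pd.concat(gf_parts).loc[meals.index]

    if metrics_in_g and metric_parts:
        mtab = pd.concat(metric_parts, ignore_index=True)
        mtab = mtab.drop(columns=["day_index"]).rename(
            columns={c: f"cum_{c}" for c in mtab.columns if c not in ("participant_id", "day")}
        )
        meal_day = np.floor(meals["t_min"].to_numpy() / MINUTES_PER_DAY).astype(int)
        key = pd.DataFrame(
            {"participant_id": meals["participant_id"].to_numpy(), "day": meal_day},
            index=meals.index,
        )
        joined = key.merge(mtab, on=["participant_id", "day"], how="left").set_index(key.index)
        gfeat = pd.concat([gfeat, joined.drop(columns=["participant_id", "day"])], axis=1)

    valid = ppgr["valid"].fillna(False).astype(bool)
    counts["meals_ppgr_valid"] = int(valid.sum())

    meta_cols = ["participant_id", "timestamp", "t_min", "meal_timing", "standardized_label"]
    obs = meals.loc[valid, meta_cols].copy()
    obs["target_iauc"] = ppgr.loc[valid, "iauc_2h"].astype(float)
    if len(bundle.truth_meals):
        truth = bundle.truth_meals.copy()
        obs = obs.merge(truth, on=["participant_id", "timestamp"], how="left")
        obs.index = meals.index[valid]

    per_meal = {
        "G": gfeat.loc[valid.index[valid]],
        "Dc": diet_feats.loc[valid.index[valid], diet_groups["Dc"]],
        "Dt": diet_feats.loc[valid.index[valid], diet_groups["Dt"]],
        "A": _activity_features(meals.loc[valid], bundle.activity),
    }
    personal = bundle.personal.copy()
    if len(personal):
        personal["sex_female"] = (personal["sex"] == "F").astype(float)
        personal = personal[["participant_id", "age", "sex_female", "bmi", "weight_kg", "height_cm"]]
    table = build_feature_table(
        obs.reset_index(drop=True),
        {g: f.reset_index(drop=True) for g, f in per_meal.items()},
        {"P": personal, "M": bundle.microbiome},
    )
    return table, counts


# ---------------------------------------------------------------------------
# File-based pipeline


def _config_hash(config: RunConfig) -> str:
    # out_dir does not affect results; leaving it out keeps manifests
    # byte-identical across runs into different directories
    blob = json.dumps(config.model_dump(exclude={"out_dir"}), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _parse_combo(label: str) -> tuple[str, ...]:
    return ("carbs_only",) if label == "carbs_only" else tuple(label.split("+"))


def _write(df: pd.DataFrame, path: Path, fmt: str) -> None:
    if fmt == "parquet":
        df.to_parquet(path.with_suffix(".parquet"), index=False)
    else:
        df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%SZ")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    man_path = out / "run_manifest.json"
    old = json.loads(man_path.read_text()) if man_path.exists() else {}
    reuse = old.get("config_hash") == chash
    manifest: dict = {
        "config_hash": chash,
        "seed": config.seed,
        "version": __version__,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": dict(old.get("stages", {})) if reuse else {},
        "row_counts": dict(old.get("row_counts", {})) if reuse else {},
    }

    def done(stage: str, outputs: list[Path]) -> bool:
        return (
            reuse
            and manifest["stages"].get(stage) == "ok"
            and all(p.exists() for p in outputs)
        )

    cohort_dir = out / "cohort"
    sim_cfg = config.simulation.model_copy(
        update={"seed": stage_seed(config.seed, "simulate")}
    )
    bundle = None
    if config.stages.simulate:
        if done("simulate", [cohort_dir / "traces.csv"]):
            log.info("simulate: up to date, skipping")
        else:
            bundle = simulate_cohort(sim_cfg)
            write_cohort(bundle, cohort_dir, config.format)
            manifest["stages"]["simulate"] = "ok"
            manifest["row_counts"]["trace_samples"] = len(bundle.traces)
            manifest["row_counts"]["meals_logged"] = len(bundle.meals)

    table = None
    feat_path = out / "feature_table.csv"
    if config.stages.features:
        if done("features", [feat_path]):
            log.info("features: up to date, skipping")
        else:
            bundle = read_cohort(cohort_dir, sim_cfg)
            table, counts = cohort_feature_table(bundle, config.metrics_in_g)
            manifest["row_counts"].update(counts)
            _write(table.df, feat_path, config.format)
            _write(table.mask, out / "feature_mask.csv", config.format)
            (out / "feature_groups.json").write_text(
                json.dumps(table.groups, indent=2, sort_keys=True)
            )
            manifest["stages"]["features"] = "ok"

    def load_table() -> FeatureTable:
        nonlocal table
        if table is None:
            df = pd.read_csv(feat_path, parse_dates=["timestamp"])
            mask = pd.read_csv(out / "feature_mask.csv")
            groups = json.loads((out / "feature_groups.json").read_text())
            table = FeatureTable(df=df, groups=groups, mask=mask.astype(bool))
        return table

    combos = (
        [_parse_combo(c) for c in config.combos] if config.combos else DEFAULT_COMBOS
    )
    evals = {}
    train_combo = ("G", "Dc", "Dt", "P")
    spec = config.training.model_copy(update={"seed": stage_seed(config.seed, "train")})
    if config.stages.train and not done("train", [out / "evaluations.json"]):
        tab = load_table()
        rows = tab.combo_rows(train_combo)
        cols = tab.combo_columns(train_combo)
        ev = train_and_evaluate(rows, cols, spec, "+".join(train_combo), config.median_impute)
        evals["+".join(train_combo)] = ev
        (out / "evaluations.json").write_text(
            json.dumps({ev.combo: ev.to_dict()}, indent=2, sort_keys=True)
        )
        manifest["stages"]["train"] = "ok"
        manifest["row_counts"]["train_rows"] = ev.n_observations

    if config.stages.ablate and not done("ablate", [out / "ablation_table.csv"]):
        tab = load_table()
        ab_spec = spec.model_copy(update={"seed": stage_seed(config.seed, "ablate")})
        ab_table, ab_evals = ablation(tab, ab_spec, combos, config.median_impute)
        evals.update(ab_evals)
        _write(ab_table, out / "ablation_table.csv", "csv")
        manifest["stages"]["ablate"] = "ok"

    if config.stages.ols and not done("ols", [out / "ols_report.json"]):
        tab = load_table()
        rows = tab.combo_rows(("Dc",))
        report = macronutrient_ols(rows)
        (out / "ols_report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        manifest["stages"]["ols"] = "ok"

    if config.stages.variance and not done("variance", [out / "variance_report.csv"]):
        tab = load_table()
        _write(variance_report(tab), out / "variance_report.csv", "csv")
        manifest["stages"]["variance"] = "ok"

    if config.stages.explain and not done("explain", [out / "summary_rank.csv"]):
        tab = load_table()
        label = "+".join(train_combo)
        if label in evals and evals[label].model is not None:
            model = evals[label].model
        else:
            rows = tab.combo_rows(train_combo)
            cols = tab.combo_columns(train_combo)
            ev = train_and_evaluate(rows, cols, spec, label, config.median_impute)
            model = ev.model
        rows = tab.combo_rows(train_combo)
        cols = tab.combo_columns(train_combo)
        attr = attribute(model, rows, cols)
        _write(attr.ranking, out / "summary_rank.csv", "csv")
        for f, dep in attr.dependence.items():
            _write(dep, out / f"dependence_{f}.csv", "csv")
        manifest["stages"]["explain"] = "ok"

    if config.stages.robustness and not done("robustness", [out / "robustness_surface.csv"]):
        tab = load_table()
        rows = tab.combo_rows(("G", "Dc", "Dt"))
        cols = tab.combo_columns(("G", "Dc", "Dt"))
        surf = robustness_surface(
            rows,
            cols,
            config.robustness_participant_counts,
            config.robustness_train_fractions,
            config.robustness_repeats,
            stage_seed(config.seed, "robustness"),
        )
        _write(surf.table, out / "robustness_surface.csv", "csv")
        manifest["stages"]["robustness"] = "ok"

    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
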