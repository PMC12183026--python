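"""Gradient-boosted-tree iAUC prediction under participant-grouped splits.

The evaluation protocol follows the study design: GroupShuffleSplit at the
participant level (test_size 0.2, 5 splits, seed 42), hyperparameters
grid-searched per feature-set combination on an inner grouped validation
split carved from the training groups, and performance reported as the
Pearson correlation R between predicted and measured iAUC.  The headline
R pools out-of-sample predictions across splits; per-split Rs are always
reported alongside.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
import xgboost as xgb
from scipy.stats import pearsonr
from sklearn.model_selection import GroupShuffleSplit
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .config import TrainingSpec

log = logging.getLogger(__name__)

TARGET = "target_iauc"

#: Default ablation list: all six single sets, the dietary pairs, the
#: headline glycemic+diet combinations and the carbohydrate-only model.
DEFAULT_COMBOS: list[tuple[str, ...]] = [
    ("G",), ("Dc",), ("Dt",), ("P",), ("M",), ("A",),
    ("Dc", "Dt"), ("G", "Dc"), ("G", "Dt"),
    ("G", "Dc", "Dt"), ("G", "Dc", "Dt", "P"), ("G", "Dc", "Dt", "M"),
    ("G", "Dc", "Dt", "A"), ("G", "Dc", "Dt", "P", "M"),
    ("G", "Dc", "Dt", "P", "M", "A"),
    ("carbs_only",),
]


def combo_label(combo: tuple[str, ...]) -> str:
    return "+".join(combo)


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if len(y_true) < 2 or np.std(y_true) == 0 or np.std(y_pred) == 0:
        return float("nan")
    return float(pearsonr(y_true, y_pred)[0])


def grouped_splits(
    groups: np.ndarray | pd.Series,
    test_size: float = 0.2,
    n_splits: int = 5,
    seed: int = 42,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Participant-level train/test index splits (no group on both sides)."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("grouped splitting needs at least 2 participants")
    gss = GroupShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed)
    return [(tr, te) for tr, te in gss.split(groups, groups=groups)]


def _fit_xgb(X: pd.DataFrame, y: np.ndarray, params: dict, seed: int) -> xgb.XGBRegressor:
    model = xgb.XGBRegressor(
        tree_method="hist",
        max_bin=64,  # CGM-derived features are smooth; coarse bins lose nothing
        n_jobs=1,
        random_state=seed,
        verbosity=0,
        **params,
    )
    model.fit(X, y)
    return model


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


@dataclass
class ModelEvaluation:
    combo: str
    n_observations: int
    per_split_r: list[float]
    pooled_r: float
    mean_split_r: float
    chosen_params: dict
    importances: dict[str, float] = field(default_factory=dict)
    model: xgb.XGBRegressor | None = None
    predictions: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "combo": self.combo,
            "n_observations": self.n_observations,
            "per_split_r": [round(r, 6) for r in self.per_split_r],
            "pooled_r": round(self.pooled_r, 6),
            "mean_split_r": round(self.mean_split_r, 6),
            "chosen_params": self.chosen_params,
        }


def train_and_evaluate(
    rows: pd.DataFrame,
    feature_cols: list[str],
    spec: TrainingSpec,
    label: str = "model",
    median_impute: bool = False,
) -> ModelEvaluation:
    """Grid-searched grouped-CV evaluation of one feature-set combination.

    ``rows`` must already be filtered to combo-complete observations
    (unless ``median_impute``, in which case NaNs in features are filled
    with training-side medians per split).
    """
    if len(rows) < spec.row_floor:
        raise ValueError(f"combo {label}: only {len(rows)} rows (< floor {spec.row_floor})")
    rows = rows.reset_index(drop=True)
    y = rows[TARGET].to_numpy(dtype=float)
    X = rows[feature_cols].astype(float)
    groups = rows["participant_id"].to_numpy()

    splits = grouped_splits(groups, spec.test_size, spec.n_splits, spec.seed)
    grid = _grid_points(spec.grid)
    pooled_true, pooled_pred, pooled_meta = [], [], []
    per_split_r, chosen = [], []
    for k, (tr, te) in enumerate(splits):
        Xtr, Xte = X.iloc[tr], X.iloc[te]
        if median_impute:
            med = Xtr.median()
            Xtr, Xte = Xtr.fillna(med), Xte.fillna(med)
        best = grid[0]
        if len(grid) > 1:
            inner = GroupShuffleSplit(
                n_splits=1, test_size=spec.inner_val_size, random_state=spec.seed + 1000 + k
            )
            (itr, ival), = inner.split(Xtr, groups=groups[tr])
            best_r = -np.inf
            for params in grid:
                m = _fit_xgb(Xtr.iloc[itr], y[tr][itr], params, spec.seed)
                r = pearson_r(y[tr][ival], m.predict(Xtr.iloc[ival]))
                if np.nan_to_num(r, nan=-np.inf) > best_r:
                    best_r, best = r, params
        chosen.append(best)
        model = _fit_xgb(Xtr, y[tr], best, spec.seed)
        pred = model.predict(Xte)
        per_split_r.append(pearson_r(y[te], pred))
        pooled_true.append(y[te])
        pooled_pred.append(pred)
        pooled_meta.append(rows.iloc[te][["participant_id"]].assign(split=k))

    pooled_r = pearson_r(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    modal = Counter(tuple(sorted(c.items())) for c in chosen).most_common(1)[0][0]
    modal_params = dict(modal)
    X_all = X.fillna(X.median()) if median_impute else X
    final = _fit_xgb(X_all, y, modal_params, spec.seed)
    booster = final.get_booster()
    gain = booster.get_score(importance_type="gain")
    preds = pd.concat(pooled_meta, ignore_index=True)
    preds["y_true"] = np.concatenate(pooled_true)
    preds["y_pred"] = np.concatenate(pooled_pred)
    ev = ModelEvaluation(
        combo=label,
        n_observations=len(rows),
        per_split_r=per_split_r,
        pooled_r=pooled_r,
        mean_split_r=float(np.nanmean(per_split_r)),
        chosen_params=modal_params,
        importances=gain,
        model=final,
        predictions=preds,
    )
    log.info("%s: n=%d pooled R=%.3f (splits %s)", label, len(rows), pooled_r,
             [f"{r:.3f}" for r in per_split_r])
    return ev


def _combo_data(table, combo: tuple[str, ...]) -> tuple[pd.DataFrame, list[str]]:
    """Rows and feature columns for a combo; 'carbs_only' is the degenerate
    single-feature model using the Dc carbohydrate column."""
    if combo == ("carbs_only",):
        rows = table.combo_rows(("Dc",))
        return rows, ["carbs_g"]
    return table.combo_rows(combo), table.combo_columns(combo)


def ablation(
    table,
    spec: TrainingSpec,
    combos: list[tuple[str, ...]] | None = None,
    median_impute: bool = False,
) -> tuple[pd.DataFrame, dict[str, ModelEvaluation]]:
    """One grouped-CV evaluation per feature-set combination, sorted by R."""
    combos = combos if combos is not None else DEFAULT_COMBOS
    evals: dict[str, ModelEvaluation] = {}
    rows_out = []
    for combo in combos:
        label = combo_label(combo)
        data, cols = _combo_data(table, combo)
        try:
            ev = train_and_evaluate(data, cols, spec, label, median_impute)
        except ValueError as err:
            log.warning("skipping %s: %s", label, err)
            continue
        evals[label] = ev
        rows_out.append(
            {"combo": label, "n_observations": ev.n_observations,
             "pooled_r": ev.pooled_r, "mean_split_r": ev.mean_split_r}
        )
    out = pd.DataFrame(rows_out).sort_values("pooled_r", ascending=False).reset_index(drop=True)
    return out, evals


def mealtime_models(
    table,
    spec: TrainingSpec,
    combo: tuple[str, ...] = ("G", "Dc", "Dt", "P"),
) -> dict[str, ModelEvaluation]:
    """Per-stratum models: breakfast / lunch / dinner, plus standardized
    vs regular breakfast substrata."""
    rows, cols = _combo_data(table, combo)
    strata: dict[str, pd.DataFrame] = {
        s: rows[rows["meal_timing"] == s] for s in ("breakfast", "lunch", "dinner")
    }
    bk = strata["breakfast"]
    if "standardized_label" in rows.columns:
        strata["breakfast_standardized"] = bk[bk["standardized_label"].notna()]
        strata["breakfast_regular"] = bk[bk["standardized_label"].isna()]
    out = {}
    for name, sub in strata.items():
        try:
            out[name] = train_and_evaluate(sub, cols, spec, f"{combo_label(combo)}|{name}")
        except ValueError as err:
            log.warning("stratum %s skipped: %s", name, err)
    return out


@dataclass
class OlsReport:
    params: dict[str, float]
    bse: dict[str, float]
    vif: dict[str, float]
    n: int
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: round(v, 6) for k, v in self.params.items()},
            "standard_errors": {k: round(v, 6) for k, v in self.bse.items()},
            "vif": {k: round(v, 4) for k, v in self.vif.items()},
            "n": self.n,
            "r_squared": round(self.r_squared, 6),
        }


def macronutrient_ols(rows: pd.DataFrame, target: str = TARGET) -> OlsReport:
    """OLS of iAUC on carbohydrate, fat and protein grams (with intercept).

    VIFs are computed first; any VIF >= 5 only warns (the study reports
    all VIFs below 5 as a multicollinearity check).
    """
    if len(rows) < 10:
        raise ValueError(f"macronutrient OLS needs >= 10 rows, got {len(rows)}")
    predictors = ["carbs_g", "fat_g", "protein_g"]
    X = sm.add_constant(rows[predictors].astype(float))
    vif = {}
    for i, name in enumerate(X.columns):
        if name == "const":
            continue
        vif[name] = float(variance_inflation_factor(X.to_numpy(), i))
    high = {k: v for k, v in vif.items() if v >= 5}
    if high:
        log.warning("VIF >= 5 for %s", high)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError("perfectly collinear macronutrient predictors")
    fit = sm.OLS(rows[target].astype(float), X).fit()
    return OlsReport(
        params=dict(fit.params),
        bse=dict(fit.bse),
        vif=vif,
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )


def variance_explained(
    rows: pd.DataFrame, feature_cols: list[str], label: str = ""
) -> float:
    """In-sample R^2 of a linear model of iAUC on one feature group.

    Collinear columns are dropped (QR pivot) with a warning.
    """
    X = rows[feature_cols].astype(float).to_numpy()
    keep = ~np.isnan(X).any(axis=0)
    X = X[:, keep]
    cols = [c for c, k in zip(feature_cols, keep) if k]
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # pivoted QR to find an independent column subset
        _, _, piv = scipy.linalg.qr(Xc, pivoting=True)
        keep_idx = sorted(piv[:rank])
        dropped = [cols[i - 1] for i in range(1, Xc.shape[1]) if i not in keep_idx]
        log.warning("%s: dropping collinear columns %s", label, dropped)
        Xc = Xc[:, keep_idx]
    fit = sm.OLS(rows[TARGET].astype(float), Xc).fit()
    return float(fit.rsquared)


def variance_report(table, strata: bool = True) -> pd.DataFrame:
    """R^2 of each feature group, overall and per meal-time stratum."""
    recs = []
    strat_values = ["all"] + (["breakfast", "lunch", "dinner"] if strata else [])
    for g, cols in table.groups.items():
        if not cols:
            continue
        for s in strat_values:
            rows = table.combo_rows((g,))
            if s != "all":
                rows = rows[rows["meal_timing"] == s]
            if len(rows) < len(cols) + 5:
                continue
            r2 = variance_explained(rows, cols, f"{g}|{s}")
            recs.append({"group": g, "stratum": s, "r_squared": r2, "n": len(rows)})
    return pd.DataFrame(recs)
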