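"""Tree-based additive feature attribution and data-size robustness maps.

Attributions are exact TreeSHAP values computed by xgboost's native
``pred_contribs`` path enumeration: for every row, base value plus the sum
of per-feature attributions equals the model prediction (in mmol·min/L of
predicted iAUC).  The robustness surface retrains a fixed-hyperparameter
model over a grid of participant counts x training fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .modeling import TARGET, pearson_r

log = logging.getLogger(__name__)

#: Features whose attribution-vs-value dependence is exported by default.
DEFAULT_DEPENDENCE_FEATURES = (
    "carbs_g",
    "glucose_at_meal",
    "trend_4h",
    "time_since_last_meal_min",
    "energy_past_3h_kcal",
    "protein_carb_ratio",
)


class UnsupportedModelError(TypeError):
    """Attribution requires a tree-ensemble (xgboost) model."""


@dataclass
class AttributionResult:
    values: pd.DataFrame  # one column per feature, one row per observation
    base_value: float
    ranking: pd.DataFrame  # feature, mean |attribution|, descending
    dependence: dict[str, pd.DataFrame] = field(default_factory=dict)
    predictions: np.ndarray | None = None

    def top(self, k: int = 15) -> pd.DataFrame:
        return self.ranking.head(k)


def attribute(
    model,
    rows: pd.DataFrame,
    feature_cols: list[str],
    dependence_features: tuple[str, ...] = DEFAULT_DEPENDENCE_FEATURES,
) -> AttributionResult:
    """Exact per-row, per-feature attribution of model predictions."""
    if isinstance(model, xgb.XGBRegressor):
        booster = model.get_booster()
    elif isinstance(model, xgb.Booster):
        booster = model
    else:
        raise UnsupportedModelError(
            f"tree attribution supports xgboost models, got {type(model).__name__}"
        )
    X = rows[feature_cols].astype(float)
    dm = xgb.DMatrix(X, feature_names=feature_cols)
    contribs = booster.predict(dm, pred_contribs=True)
    values = pd.DataFrame(contribs[:, :-1], columns=feature_cols, index=rows.index)
    base = float(np.mean(contribs[:, -1]))
    preds = contribs.sum(axis=1)
    ranking = (
        values.abs().mean().sort_values(ascending=False).rename("mean_abs_attribution").reset_index()
    ).rename(columns={"index": "feature"})
    dep = {}
    for f in dependence_features:
        if f in feature_cols:
            dep[f] = pd.DataFrame(
                {"feature_value": X[f].to_numpy(), "attribution": values[f].to_numpy()}
            )
    return AttributionResult(
        values=values, base_value=base, ranking=ranking, dependence=dep, predictions=preds
    )


@dataclass
class RobustnessSurface:
    table: pd.DataFrame  # n_participants, train_fraction, mean_r, sd_r, n_repeats

    def grid(self) -> pd.DataFrame:
        return self.table.pivot(index="n_participants", columns="train_fraction", values="mean_r")


def robustness_surface(
    rows: pd.DataFrame,
    feature_cols: list[str],
    participant_counts: list[int],
    train_fractions: list[float],
    n_repeats: int = 3,
    seed: int = 42,
    model_params: dict | None = None,
) -> RobustnessSurface:
    """Mean +- SD of grouped test R over (participant count, train fraction).

    Each repetition subsamples participants with a derived seed, splits
    train/test group-wise at the requested fraction, and fits one
    fixed-hyperparameter model (re-tuning per cell would confound the
    size effect with tuning noise).
    """
    params = model_params or {
        "n_estimators": 300, "learning_rate": 0.05, "max_depth": 6,
        "subsample": 0.9, "colsample_bytree": 0.9,
    }
    pids = np.asarray(sorted(rows["participant_id"].unique()))
    if max(participant_counts) > pids.size:
        raise ValueError(
            f"requested {max(participant_counts)} participants, cohort has {pids.size}"
        )
    if sorted(participant_counts) != list(participant_counts) or sorted(
        train_fractions
    ) != list(train_fractions):
        raise ValueError("grid axes must be strictly increasing")
    recs = []
    for ic, n_p in enumerate(participant_counts):
        for jf, frac in enumerate(train_fractions):
            rs = []
            for rep in range(n_repeats):
                ss = np.random.SeedSequence([seed, ic, jf, rep])
                rng = np.random.default_rng(ss)
                cell_seed = int(ss.generate_state(1)[0] % (2**31))
                chosen = rng.choice(pids, size=n_p, replace=False)
                sub = rows[rows["participant_id"].isin(chosen)]
                groups = sub["participant_id"].to_numpy()
                uniq = np.unique(groups)
                n_train = max(1, int(round(frac * uniq.size)))
                if uniq.size - n_train < 2:
                    continue  # cell unavailable: < 2 test participants
                train_p = set(rng.permutation(uniq)[:n_train])
                tr = np.array([g in train_p for g in groups])
                model = xgb.XGBRegressor(
                    tree_method="hist", max_bin=64, n_jobs=1, random_state=cell_seed,
                    verbosity=0, **params,
                )
                X = sub[feature_cols].astype(float)
                y = sub[TARGET].to_numpy(dtype=float)
                model.fit(X[tr], y[tr])
                rs.append(pearson_r(y[~tr], model.predict(X[~tr])))
            recs.append(
                {
                    "n_participants": n_p,
                    "train_fraction": frac,
                    "mean_r": float(np.mean(rs)) if rs else np.nan,
                    "sd_r": float(np.std(rs, ddof=1)) if len(rs) > 1 else np.nan,
                    "n_repeats": len(rs),
                }
            )
    return RobustnessSurface(pd.DataFrame(recs))
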