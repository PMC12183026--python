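"""Grouped splitting, GBT evaluation, OLS, and variance explanation."""

import numpy as np
import pandas as pd
import pytest

from ppgr.config import REDUCED_GRID, TrainingSpec
from ppgr.modeling import (
    grouped_splits,
    macronutrient_ols,
    mealtime_models,
    train_and_evaluate,
    variance_explained,
)

SMALL_SPEC = TrainingSpec(grid=REDUCED_GRID, n_splits=3, row_floor=20)


def make_rows(n_participants=30, per=30, noise=0.0, seed=0, random_effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        u = rng.normal(0, random_effect) if random_effect else 0.0
        x1 = rng.uniform(0, 100, per)
        x2 = rng.uniform(0, 100, per)
        y = 2.0 * x1 + u + rng.normal(0, noise, per)
        rows.append(pd.DataFrame({"participant_id": f"P{p:03d}", "x1": x1, "x2": x2,
                                  "target_iauc": y}))
    return pd.concat(rows, ignore_index=True)


# --- grouped splits --------------------------------------------------------

def test_grouped_splits_fraction_disjoint_deterministic():
    groups = np.repeat([f"P{i}" for i in range(10)], 5)
    splits = grouped_splits(groups, test_size=0.2, n_splits=5, seed=42)
    for tr, te in splits:
        tr_p, te_p = set(groups[tr]), set(groups[te])
        assert len(te_p) == 2
        assert tr_p.isdisjoint(te_p)
    again = grouped_splits(groups, test_size=0.2, n_splits=5, seed=42)
    for (a, _), (b, _) in zip(splits, again):
        assert np.array_equal(a, b)


def test_grouped_splits_need_two_participants():
    with pytest.raises(ValueError):
        grouped_splits(np.array(["P1"] * 10))


# --- train and evaluate ----------------------------------------------------

def test_learnable_identity_reaches_high_r():
    rows = make_rows(noise=0.0)
    ev = train_and_evaluate(rows, ["x1"], SMALL_SPEC, "identity")
    assert ev.pooled_r > 0.99
    assert ev.n_observations == len(rows)


def test_pure_noise_target_near_zero_r():
    # null distribution of pooled R at n=2000: many small groups keep the
    # grouped-pooling variance near the iid 1/sqrt(n) scale
    rng = np.random.default_rng(1)
    rs = []
    for seed in range(20):
        rows = make_rows(n_participants=40, per=50, seed=seed + 100)
        rows["target_iauc"] = rng.normal(0, 1, len(rows))  # independent of x1/x2
        ev = train_and_evaluate(rows, ["x1", "x2"], SMALL_SPEC, "noise")
        rs.append(ev.pooled_r)
    assert all(abs(r) < 0.1 for r in rs)
    assert abs(np.mean(rs)) < 0.03


def test_duplicating_rows_leaves_grouped_r_unchanged():
    # grouping is at the participant level: duplicating rows must not move
    # anyone across the split, and the evaluated R stays put up to fitting
    # jitter from the duplicated training set
    rows = make_rows(n_participants=15, per=20, noise=20.0, random_effect=30.0)
    ev1 = train_and_evaluate(rows, ["x1"], SMALL_SPEC, "base")
    doubled = pd.concat([rows, rows], ignore_index=True)
    ev2 = train_and_evaluate(doubled, ["x1"], SMALL_SPEC, "doubled")
    for (_, te1), (_, te2) in zip(
        grouped_splits(rows["participant_id"], SMALL_SPEC.test_size, SMALL_SPEC.n_splits,
                       SMALL_SPEC.seed),
        grouped_splits(doubled["participant_id"], SMALL_SPEC.test_size, SMALL_SPEC.n_splits,
                       SMALL_SPEC.seed),
    ):
        assert set(rows["participant_id"].iloc[te1]) == set(doubled["participant_id"].iloc[te2])
    assert ev2.pooled_r == pytest.approx(ev1.pooled_r, abs=0.02)


def test_row_floor_error_names_combo():
    rows = make_rows(n_participants=2, per=3)
    with pytest.raises(ValueError, match="tiny_combo"):
        train_and_evaluate(rows, ["x1"], SMALL_SPEC, "tiny_combo")


def test_grid_search_selects_from_inner_validation():
    rows = make_rows(n_participants=20, per=25, noise=5.0)
    spec = TrainingSpec(
        grid={"n_estimators": [1000], "learning_rate": [0.005, 0.01], "max_depth": [6],
              "subsample": [0.9], "colsample_bytree": [0.9]},
        n_splits=2, row_floor=20,
    )
    ev = train_and_evaluate(rows, ["x1"], spec, "grid")
    assert ev.chosen_params["learning_rate"] in (0.005, 0.01)
    assert ev.pooled_r > 0.9


# --- OLS -------------------------------------------------------------------

def test_ols_exact_linear_relation():
    rng = np.random.default_rng(2)
    rows = pd.DataFrame({
        "carbs_g": rng.uniform(10, 100, 200),
        "fat_g": rng.uniform(0, 40, 200),
        "protein_g": rng.uniform(0, 40, 200),
    })
    rows["target_iauc"] = 2.0 * rows["carbs_g"]
    rep = macronutrient_ols(rows)
    assert rep.params["carbs_g"] == pytest.approx(2.0, abs=1e-9)
    assert rep.bse["carbs_g"] == pytest.approx(0.0, abs=1e-9)


def test_ols_orthogonal_predictors_unit_vif():
    n = 64
    base = np.arange(n)
    rows = pd.DataFrame({
        "carbs_g": np.where(base % 2 == 0, 1.0, -1.0),
        "fat_g": np.where(base % 4 < 2, 1.0, -1.0),
        "protein_g": np.where(base % 8 < 4, 1.0, -1.0),
    })
    rows["target_iauc"] = rows.sum(axis=1)
    rep = macronutrient_ols(rows)
    for v in rep.vif.values():
        assert v == pytest.approx(1.0, abs=1e-9)


def test_ols_collinear_predictors_raise():
    rng = np.random.default_rng(3)
    rows = pd.DataFrame({"carbs_g": rng.uniform(10, 100, 50)})
    rows["fat_g"] = 0.5 * rows["carbs_g"]
    rows["protein_g"] = rng.uniform(0, 40, 50)
    rows["target_iauc"] = rows["carbs_g"]
    with pytest.raises(np.linalg.LinAlgError):
        macronutrient_ols(rows)


def test_ols_needs_ten_rows():
    rows = pd.DataFrame({"carbs_g": [1.0] * 5, "fat_g": [1.0] * 5,
                         "protein_g": [1.0] * 5, "target_iauc": [1.0] * 5})
    with pytest.raises(ValueError):
        macronutrient_ols(rows)


# --- variance explanation --------------------------------------------------

def test_variance_r2_one_for_determining_feature():
    rows = make_rows(n_participants=5, per=20, noise=0.0)
    assert variance_explained(rows, ["x1"]) == pytest.approx(1.0, abs=1e-12)


def test_variance_r2_near_zero_for_independent_group():
    rng = np.random.default_rng(4)
    rows = pd.DataFrame({"x1": rng.normal(size=2000), "x2": rng.normal(size=2000)})
    rows["target_iauc"] = rng.normal(size=2000)
    assert variance_explained(rows, ["x1", "x2"]) <= 0.02


def test_variance_nested_groups_monotone(rng):
    n = 500
    rows = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    rows["target_iauc"] = rows["a"] + 0.5 * rows["b"] + rng.normal(0, 1, n)
    ra = variance_explained(rows, ["a"])
    rb = variance_explained(rows, ["b"])
    rab = variance_explained(rows, ["a", "b"])
    assert rab >= max(ra, rb) - 1e-12


def test_variance_drops_collinear_columns(caplog):
    rng = np.random.default_rng(5)
    rows = pd.DataFrame({"a": rng.normal(size=100)})
    rows["b"] = 2.0 * rows["a"]
    rows["target_iauc"] = rows["a"] + rng.normal(0, 0.1, 100)
    with caplog.at_level("WARNING"):
        r2 = variance_explained(rows, ["a", "b"], "collinear")
    assert 0.9 < r2 <= 1.0
    assert "collinear" in caplog.text


# --- meal-time strata ------------------------------------------------------

def _fake_table(timings, n_per=60, standardized_frac=0.3):
    rng = np.random.default_rng(6)
    frames = []
    for timing in timings:
        x = rng.uniform(0, 100, n_per)
        frames.append(pd.DataFrame({
            "participant_id": rng.choice([f"P{i}" for i in range(12)], n_per),
            "meal_timing": timing,
            "standardized_label": np.where(
                (timing == "breakfast") & (rng.random(n_per) < standardized_frac),
                "white_bread", None),
            "x1": x,
            "target_iauc": 2 * x + rng.normal(0, 5, n_per),
        }))
    df = pd.concat(frames, ignore_index=True)

    class Stub:
        def combo_rows(self, combo):
            return df

        def combo_columns(self, combo):
            return ["x1"]

    return Stub(), df


def test_mealtime_strata_partition_and_skip(caplog):
    table, df = _fake_table(["breakfast", "lunch", "dinner"])
    spec = TrainingSpec(grid=REDUCED_GRID, n_splits=2, row_floor=20)
    out = mealtime_models(table, spec, combo=("Dc",))
    core = {k: v for k, v in out.items() if k in ("breakfast", "lunch", "dinner")}
    assert sum(ev.n_observations for ev in core.values()) == len(df)
    # all-breakfast data: lunch/dinner strata are skipped with warnings
    table_b, _ = _fake_table(["breakfast"])
    with caplog.at_level("WARNING"):
        out_b = mealtime_models(table_b, spec, combo=("Dc",))
    assert "breakfast" in out_b and "lunch" not in out_b and "dinner" not in out_b
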