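"""Synthetic-cohort generator: determinism, structure, truth model."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from conftest import noiseless_config
from ppgr.config import DEFAULT_STANDARDIZED_MEALS, SimulationConfig
from ppgr.simulate import (
    bump_amplitude,
    inject_missingness,
    kernel,
    kernel_window_area,
    meal_response_truth,
    render_trace,
    simulate_cohort,
)


def test_fixed_seed_is_bit_identical():
    cfg = SimulationConfig(n_participants=3, n_days=14, seed=42)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    for name in ("traces", "meals", "personal", "microbiome", "activity", "truth_meals"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))


def test_no_dropout_gives_full_grid():
    cfg = noiseless_config(n_participants=2, n_days=3, seed=1, standardized_days=(2,))
    bundle = simulate_cohort(cfg)
    per = bundle.traces.groupby("participant_id").size()
    assert (per == 3 * 96 + 1).all()


def test_default_betas_match_reported_population_effects():
    cfg = SimulationConfig()
    assert (cfg.beta_carb, cfg.beta_fat, cfg.beta_protein) == (1.08, -1.54, -3.27)


def test_standardized_meals_have_50g_carbs():
    for spec in DEFAULT_STANDARDIZED_MEALS.values():
        assert spec.carbs == pytest.approx(50.0, abs=1.0)


def test_invalid_config_names_field():
    with pytest.raises(ValidationError, match="missing_rate"):
        SimulationConfig(missing_rate=1.5)
    with pytest.raises(ValidationError, match="n_days"):
        SimulationConfig(n_days=1)
    with pytest.raises(ValidationError, match="beta_carb"):
        SimulationConfig(beta_carb=-1.0)


# --- truth model -----------------------------------------------------------

def test_truth_empty_meal_and_multiplicative_structure():
    cfg = SimulationConfig(beta0=0.0, circadian_gain=0.0)
    assert meal_response_truth(0, 0, 0, 1.0, 12.0, cfg) == 0.0
    t1 = meal_response_truth(50, 5, 5, 1.0, 12.0, cfg)
    t2 = meal_response_truth(50, 5, 5, 2.0, 12.0, cfg)
    assert t2 == pytest.approx(2.0 * t1)


def test_truth_direct_evaluation_carbs_only():
    cfg = SimulationConfig(beta0=0.0, circadian_gain=0.0, beta_carb=1.08)
    assert meal_response_truth(50, 0, 0, 1.0, 7.0, cfg) == pytest.approx(54.0)


def test_truth_zero_when_linear_part_negative():
    cfg = SimulationConfig(beta0=0.0, circadian_gain=0.0)
    assert meal_response_truth(1.0, 50.0, 50.0, 1.0, 12.0, cfg) == 0.0


def test_truth_rejects_negative_grams():
    with pytest.raises(ValueError):
        meal_response_truth(-1.0, 0, 0, 1.0, 12.0, SimulationConfig())


def test_bump_amplitude_inverts_window_area():
    tau = 35.0
    a = bump_amplitude(120.0, tau)
    # numeric check of the closed-form window area
    tgrid = np.linspace(0, 120.0, 200001)
    numeric = np.trapezoid(kernel(tgrid / tau), tgrid)
    assert a * numeric == pytest.approx(120.0, rel=1e-6)
    assert kernel_window_area(tau) == pytest.approx(numeric, rel=1e-6)


# --- rendering -------------------------------------------------------------

def test_render_zero_meals_flat_baseline():
    cfg = noiseless_config()
    grid = np.arange(0.0, 1441.0, 15.0)
    rng = np.random.default_rng(0)
    vals = render_trace(grid, np.array([]), np.array([]), np.array([]), 5.2, cfg, rng)
    assert np.allclose(vals, 5.2)


def test_render_superposition_linearity():
    cfg = noiseless_config()
    grid = np.arange(0.0, 1441.0, 15.0)
    rng = np.random.default_rng(0)
    base = 5.0
    one = render_trace(grid, np.array([300.0]), np.array([1.5]), np.array([35.0]), base, cfg, rng)
    two = render_trace(grid, np.array([480.0]), np.array([2.0]), np.array([35.0]), base, cfg, rng)
    both = render_trace(
        grid, np.array([300.0, 480.0]), np.array([1.5, 2.0]), np.array([35.0, 35.0]), base, cfg, rng
    )
    assert np.allclose(both, one + two - base, atol=1e-9)


def test_render_clips_at_physiological_floor():
    cfg = noiseless_config()
    grid = np.arange(0.0, 200.0, 15.0)
    vals = render_trace(grid, np.array([]), np.array([]), np.array([]), 0.5, cfg,
                        np.random.default_rng(0))
    assert (vals >= 2.0).all()


# --- missingness -----------------------------------------------------------

def test_missingness_identity_and_empty():
    t = np.arange(0.0, 1000.0, 15.0)
    y = np.full(t.size, 5.0)
    t2, y2 = inject_missingness(t, y, 0.0, 0.0, 0)
    assert np.array_equal(t2, t) and np.array_equal(y2, y)
    t3, _ = inject_missingness(t, y, 1.0, 0.0, 0)
    assert t3.size == 0


def test_missingness_binomial_retention():
    t = np.arange(0.0, 15000.0, 15.0)  # 1000 samples
    y = np.full(t.size, 5.0)
    fracs = []
    for seed in range(20):
        t2, _ = inject_missingness(t, y, 0.1, 0.0, seed)
        fracs.append(t2.size / t.size)
    assert np.mean(fracs) == pytest.approx(0.9, abs=0.03)


def test_missingness_rejects_bad_rate():
    t = np.arange(0.0, 100.0, 15.0)
    with pytest.raises(ValueError):
        inject_missingness(t, np.full(t.size, 5.0), -0.1, 0.0, 0)


def test_long_gaps_keep_timestamps_increasing():
    t = np.arange(0.0, 7 * 1440.0, 15.0)
    y = np.full(t.size, 5.0)
    t2, _ = inject_missingness(t, y, 0.05, 2.0, 123, n_days=7)
    assert (np.diff(t2) > 0).all()
    assert t2.size < t.size


# --- side-table independence ----------------------------------------------

def test_microbiome_coupling_does_not_touch_traces_or_meals():
    base = SimulationConfig(n_participants=4, n_days=3, seed=9, microbiome_effect=0.0,
                            standardized_days=(2, 3))
    coupled = base.model_copy(update={"microbiome_effect": 0.8})
    a, b = simulate_cohort(base), simulate_cohort(coupled)
    pd.testing.assert_frame_equal(a.traces, b.traces)
    pd.testing.assert_frame_equal(a.meals, b.meals)
    # only the coupled coordinate differs
    assert not np.allclose(a.microbiome["unifrac_pc1"], b.microbiome["unifrac_pc1"])
    assert np.allclose(a.microbiome["unifrac_pc2"], b.microbiome["unifrac_pc2"])


def test_standardized_breakfasts_on_scheduled_days():
    cfg = noiseless_config(n_participants=2, n_days=7, seed=3)
    bundle = simulate_cohort(cfg)
    meals = bundle.meals
    labeled = meals[meals["standardized_label"].notna()]
    start = pd.Timestamp(cfg.start_date, tz="UTC")
    days = (labeled["timestamp"].dt.normalize() - start).dt.days + 1
    assert set(days) <= set(cfg.standardized_days)
    # one standardized breakfast per participant per scheduled day
    assert len(labeled) == 2 * len([d for d in cfg.standardized_days if d <= 7])
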