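"""iAUC target, baseline search, trends and gap handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import dense_grid_iauc
from ppgr.glycemic import (
    CoverageError,
    compute_iauc,
    fill_gaps,
    find_baseline,
    glucose_trend,
    past_iauc,
    ppgr_for_meals,
)


# --- gap filling -----------------------------------------------------------

def test_fill_gaps_inserts_midpoint_mean():
    t, y, gaps = fill_gaps(np.array([0.0, 30.0]), np.array([5.0, 6.0]))
    assert list(t) == [0.0, 15.0, 30.0]
    assert list(y) == [5.0, 5.5, 6.0]
    assert gaps == []


def test_fill_gaps_identity_on_grid():
    t = np.arange(0, 120, 15.0)
    y = np.linspace(5, 6, len(t))
    t2, y2, gaps = fill_gaps(t, y)
    assert np.array_equal(t2, t) and np.array_equal(y2, y) and gaps == []


def test_fill_gaps_leaves_long_gap_and_records_it():
    t, y, gaps = fill_gaps(np.array([0.0, 45.0]), np.array([5.0, 6.0]))
    assert list(t) == [0.0, 45.0]
    assert gaps == [(0.0, 45.0)]


# --- baseline search -------------------------------------------------------

def test_baseline_local_minimum_closest_to_meal():
    t = np.array([-30.0, -15.0, 0.0])
    assert find_baseline(t, np.array([5.2, 4.9, 5.1]), 0.0) == (-15.0, 4.9)


def test_baseline_monotone_window_falls_back_to_minimum():
    t = np.array([-30.0, -15.0, 0.0])
    assert find_baseline(t, np.array([5.4, 5.2, 5.0]), 0.0) == (0.0, 5.0)


def test_baseline_tie_broken_toward_meal():
    t = np.array([-30.0, -15.0, 0.0])
    assert find_baseline(t, np.array([4.9, 4.9, 5.1]), 0.0) == (-15.0, 4.9)


def test_baseline_requires_pre_meal_samples():
    with pytest.raises(CoverageError):
        find_baseline(np.array([10.0, 25.0]), np.array([5.0, 5.1]), 0.0)


def test_baseline_never_uses_post_meal_samples():
    # deep post-meal minimum must not leak into the baseline
    t = np.array([-30.0, -15.0, 0.0, 15.0])
    bt, bv = find_baseline(t, np.array([5.2, 5.1, 5.3, 3.0]), 0.0)
    assert bt == -15.0 and bv == 5.1


# --- iAUC ------------------------------------------------------------------

HAND_TRACE = np.array([5.0, 5.5, 7.0, 8.0, 7.5, 6.5, 6.0, 5.5, 5.0])


def test_iauc_hand_worked_nine_sample_fixture():
    t = np.arange(9) * 15.0
    assert compute_iauc(t, HAND_TRACE, 0.0, 5.0) == pytest.approx(165.0, abs=1e-12)


def test_iauc_constant_trace_is_zero():
    t = np.arange(9) * 15.0
    assert compute_iauc(t, np.full(9, 5.0), 0.0, 5.0) == 0.0


def test_iauc_dip_below_baseline_ignored():
    t = np.arange(9) * 15.0
    y = np.array([5.0, 4.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0])
    assert compute_iauc(t, y, 0.0, 5.0) == 0.0


def test_iauc_excludes_window_with_long_gap():
    t = np.array([0.0, 15.0, 75.0, 90.0, 105.0, 120.0])
    y = np.full(6, 6.0)
    with pytest.raises(CoverageError):
        compute_iauc(t, y, 0.0, 5.0)


def test_iauc_translation_invariance_and_scale_covariance(rng):
    t = np.arange(12) * 15.0
    y = 5.0 + np.abs(rng.normal(0, 1, 12))
    base = compute_iauc(t, y, 0.0, 5.0, horizon=165.0)
    shifted = compute_iauc(t, y + 3.0, 0.0, 8.0, horizon=165.0)
    scaled = compute_iauc(t, 5.0 + 2.0 * (y - 5.0), 0.0, 5.0, horizon=165.0)
    assert shifted == pytest.approx(base, rel=1e-12)
    assert scaled == pytest.approx(2.0 * base, rel=1e-12)


def test_iauc_matches_dense_grid_oracle_on_random_fixtures(rng):
    for _ in range(100):
        n = int(rng.integers(9, 30))
        t = np.arange(n) * 15.0
        y = 5.0 + rng.normal(0, 1.0, n)  # crosses baseline often
        base = float(rng.uniform(4.5, 6.0))
        ours = compute_iauc(t, y, 0.0, base, horizon=t[-1])
        oracle = dense_grid_iauc(t, y, 0.0, base, horizon=t[-1])
        assert ours == pytest.approx(oracle, abs=1e-9)
        assert ours >= 0.0


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(3.0, 12.0), min_size=9, max_size=20), st.floats(4.0, 7.0))
def test_iauc_nonnegative_and_oracle_equal_property(values, baseline):
    y = np.asarray(values)
    t = np.arange(len(y)) * 15.0
    ours = compute_iauc(t, y, 0.0, baseline, horizon=t[-1])
    assert ours >= 0.0
    assert ours == pytest.approx(dense_grid_iauc(t, y, 0.0, baseline, horizon=t[-1]), abs=1e-9)


def test_iauc_interpolates_off_grid_window_boundaries():
    # window [10, 40] over a straight line y = 5 + 0.1 t, baseline 5
    t = np.arange(0, 61, 15.0)
    y = 5.0 + 0.1 * t
    expected = 0.1 * (40**2 - 10**2) / 2  # exact integral of 0.1 t
    assert compute_iauc(t, y, 10.0, 5.0, horizon=30.0) == pytest.approx(expected, rel=1e-12)


# --- trends and past iAUC --------------------------------------------------

def test_trend_exact_line_and_constant():
    t = np.arange(0, 61, 15.0)
    assert glucose_trend(t, 5.0 + t / 60.0, 60.0, 1) == pytest.approx(1.0)
    assert glucose_trend(t, np.full(5, 5.0), 60.0, 1) == 0.0


def test_trend_closed_form_three_samples():
    t = np.array([0.0, 30.0, 60.0])
    assert glucose_trend(t, np.array([5.0, 5.2, 5.7]), 60.0, 1) == pytest.approx(0.7)


def test_trend_missing_with_single_sample():
    assert glucose_trend(np.array([0.0]), np.array([5.0]), 0.0, 1) is None


def test_past_iauc_reuses_bump_oracle_and_nests():
    # the 165-area bump placed wholly inside the prior 2 h
    t = np.arange(9) * 15.0
    assert past_iauc(t, HAND_TRACE, 120.0, 2) == pytest.approx(165.0)
    # constant trace: zero for all intervals
    tc = np.arange(0, 250, 15.0)
    for h in (1, 2, 4):
        assert past_iauc(tc, np.full(tc.size, 5.5), 240.0, h) == 0.0


def test_past_iauc_window_nesting_single_recent_bump(rng):
    # single bump inside the last hour: longer windows can only add area
    t = np.arange(0, 250, 15.0)
    y = np.full(t.size, 5.0)
    y[-3] += 2.0
    p1 = past_iauc(t, y, 240.0, 1)
    p4 = past_iauc(t, y, 240.0, 4)
    assert p1 <= p4 + 1e-12


# --- meal loop -------------------------------------------------------------

def test_ppgr_for_meals_excludes_and_reports():
    t = np.arange(0, 1441, 15.0)
    y = np.full(t.size, 5.5)
    y[40:45] += np.array([1.0, 2.0, 2.5, 1.5, 0.5])
    # meal 10 min after trace start lacks its pre-window; a meal inside a
    # 60-min outage window is excluded by the gap rule
    gap_t = np.concatenate([t[:50], t[55:]])
    gap_y = np.concatenate([y[:50], y[55:]])
    pp, gf = ppgr_for_meals(gap_t, gap_y, np.array([10.0, t[48]]))
    assert not pp.loc[0, "valid"] and pp.loc[0, "exclusion_reason"] == "no_pre_meal_samples"
    assert not pp.loc[1, "valid"] and "gap" in pp.loc[1, "exclusion_reason"]
    assert set(gf.columns) >= {"glucose_at_meal", "trend_4h", "past_iauc_2h"}


def test_ppgr_valid_meal_full_pipeline():
    t = np.arange(0, 400, 15.0)
    y = np.full(t.size, 5.0)
    y[10:19] = HAND_TRACE  # bump starting at t=150
    pp, _ = ppgr_for_meals(t, y, np.array([150.0]))
    assert pp.loc[0, "valid"]
    assert pp.loc[0, "iauc_2h"] == pytest.approx(165.0)
    assert pp.loc[0, "baseline_time"] <= 150.0
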