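"""Synthetic digital-cohort generator.

Produces CGM traces, meal logs and per-participant side tables from a known
structural meal-response model, so the whole downstream pipeline can be
validated against analytic ground truth.

Structural model for one meal with nutrient grams (C, F, P) eaten at
hour-of-day h by a participant with sensitivity s:

    iAUC_true = s * m(h) * max(0, beta0 + bC*C + bF*F + bP*P)

with m(h) = max(0, 1 + circadian_gain*(h-7)/12) a linear circadian
multiplier.  The rendered trace superposes, on a mean-reverting baseline,
one gamma-like response bump per meal,

    g_k(t) = A_k * u * exp(1 - u),   u = (t - t_k) / tau_peak,

whose amplitude A_k is chosen analytically so that the incremental area of
the noiseless bump over the 2-h post-meal window equals iAUC_true.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_STANDARDIZED_MEALS,
    DEFAULT_STANDARDIZED_SCHEDULE,
    FOOD_CLASSES,
    SimulationConfig,
    StandardizedMealSpec,
)

IAUC_WINDOW_MIN = 120.0
GLUCOSE_FLOOR = 2.0
GLUCOSE_CEIL = 30.0
MINUTES_PER_DAY = 1440

# Conventional meal hours (jittered per meal).
MEAL_HOURS = (7.5, 12.5, 19.0)
MEAL_JITTER_H = (0.5, 0.5, 0.6)


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: data tables plus ground truth."""

    traces: pd.DataFrame  # participant_id, timestamp, glucose_mmol_l
    meals: pd.DataFrame
    personal: pd.DataFrame
    microbiome: pd.DataFrame
    activity: pd.DataFrame
    truth_meals: pd.DataFrame  # participant_id, timestamp, true_iauc
    truth_participants: pd.DataFrame  # participant_id, sensitivity, baseline_level
    config: SimulationConfig = field(default_factory=SimulationConfig)


def circadian_multiplier(hour: float | np.ndarray, gain: float) -> float | np.ndarray:
    return np.maximum(0.0, 1.0 + gain * (np.asarray(hour) - 7.0) / 12.0)


def meal_response_truth(
    carbs: float,
    fat: float,
    protein: float,
    sensitivity: float,
    hour_of_day: float,
    config: SimulationConfig,
) -> float:
    """Analytic (noiseless) 2-h iAUC of one meal, mmol·min/L."""
    if min(carbs, fat, protein) < 0:
        raise ValueError("nutrient grams must be >= 0")
    linear = (
        config.beta0
        + config.beta_carb * carbs
        + config.beta_fat * fat
        + config.beta_protein * protein
    )
    m = float(circadian_multiplier(hour_of_day, config.circadian_gain))
    return sensitivity * m * max(0.0, linear)


def kernel(u: np.ndarray | float) -> np.ndarray | float:
    """Normalized response bump h(u) = (u e^(1-u))^2, peak 1 at u = 1.

    The squared-gamma shape has a lagged onset (h'(0) = 0), matching the
    delayed start of real postprandial excursions, and a lighter late
    tail than the plain gamma bump; both matter for how faithfully the
    minima-anchored 2-h window recaptures the generated area.
    """
    u = np.asarray(u, dtype=float)
    out = np.where(u > 0, (u * np.exp(1.0 - np.clip(u, 0, 50))) ** 2, 0.0)
    return out if out.ndim else float(out)


def kernel_window_area(tau: float, window: float = IAUC_WINDOW_MIN) -> float:
    """Closed-form integral of the bump over [0, window] in t-units (u = t/tau)."""
    x = window / tau
    return tau * (np.e**2 / 4.0) * (1.0 - np.exp(-2 * x) * (1.0 + 2 * x + 2 * x**2))


def bump_amplitude(true_iauc: float, tau: float) -> float:
    """Peak height (mmol/L) so the 2-h bump area equals ``true_iauc``."""
    return true_iauc / kernel_window_area(tau)


def response_bump(t: np.ndarray, t_meal: float, amplitude: float, tau: float) -> np.ndarray:
    return amplitude * kernel((t - t_meal) / tau)


def render_trace(
    grid_minutes: np.ndarray,
    meal_times: np.ndarray,
    amplitudes: np.ndarray,
    taus: np.ndarray,
    baseline_level: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noisy, quantized glucose values on the sample grid (mmol/L)."""
    g = np.full(grid_minutes.shape, float(baseline_level))
    # slow mean-reverting (AR(1)/OU) wiggle around the personal level
    if config.baseline_wiggle_sd > 0:
        tau_b = 180.0  # minutes; slow relative to meal responses
        phi = np.exp(-config.sample_interval / tau_b)
        eps = rng.normal(0.0, 1.0, size=grid_minutes.size)
        w = np.empty(grid_minutes.size)
        w[0] = eps[0]
        for i in range(1, grid_minutes.size):
            w[i] = phi * w[i - 1] + np.sqrt(1 - phi**2) * eps[i]
        g += config.baseline_wiggle_sd * w
    for t_k, a_k, tau_k in zip(meal_times, amplitudes, taus):
        g += response_bump(grid_minutes, t_k, a_k, tau_k)
    if config.noise_sd > 0:
        g += rng.normal(0.0, config.noise_sd, size=grid_minutes.size)
    if config.quantization > 0:
        g = np.round(g / config.quantization) * config.quantization
    return np.clip(g, GLUCOSE_FLOOR, GLUCOSE_CEIL)


def inject_missingness(
    grid_minutes: np.ndarray,
    values: np.ndarray,
    missing_rate: float,
    long_gap_rate: float,
    rng: np.random.Generator | int,
    n_days: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop random single samples plus Poisson-count 60-240 min outages."""
    if not (0 <= missing_rate <= 1) or long_gap_rate < 0:
        raise ValueError("missing_rate must be in [0,1] and long_gap_rate >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    keep = np.ones(grid_minutes.size, dtype=bool)
    if missing_rate > 0:
        keep &= rng.random(grid_minutes.size) >= missing_rate
    if long_gap_rate > 0 and grid_minutes.size:
        span = grid_minutes[-1] - grid_minutes[0]
        if n_days is None:
            n_days = span / MINUTES_PER_DAY
        n_gaps = rng.poisson(long_gap_rate * n_days / 7.0)
        for _ in range(n_gaps):
            start = grid_minutes[0] + rng.uniform(0, max(span, 1))
            length = rng.uniform(60.0, 240.0)
            keep &= ~((grid_minutes > start) & (grid_minutes < start + length))
    return grid_minutes[keep], values[keep]


def _draw_adlib_meal(rng: np.random.Generator, cfg: SimulationConfig) -> dict:
    carbs = float(rng.lognormal(cfg.carb_log_mean, cfg.carb_log_sd))
    fat = float(rng.lognormal(cfg.fat_log_mean, cfg.fat_log_sd))
    protein = float(rng.lognormal(cfg.protein_log_mean, cfg.protein_log_sd))
    fiber = float(rng.lognormal(cfg.fiber_log_mean, cfg.fiber_log_sd))
    energy = 4.0 * carbs + 9.0 * fat + 4.0 * protein + 2.0 * fiber
    quantity = (carbs + fat + protein + fiber) * float(rng.uniform(2.5, 4.5))
    shares = rng.dirichlet([2.0, 2.0, 1.0, 1.0, 2.0, 1.0])
    classes = {cls: quantity * s for cls, s in zip(FOOD_CLASSES, shares)}
    return dict(
        carbs_g=carbs, fat_g=fat, protein_g=protein, fiber_g=fiber,
        energy_kcal=energy, eaten_quantity_g=quantity,
        standardized_label=None, form="solid", **classes,
    )


def _standardized_meal(spec: StandardizedMealSpec) -> dict:
    fiber = 2.0 if spec.form == "solid" else 0.0
    energy = 4.0 * spec.carbs + 9.0 * spec.fat + 4.0 * spec.protein + 2.0 * fiber
    quantity = {"glucose_drink": 250.0, "white_bread": 120.0, "bread_butter": 140.0}.get(
        spec.label, 120.0
    )
    classes = dict.fromkeys(FOOD_CLASSES, 0.0)
    if spec.label == "glucose_drink":
        classes["non_alcoholic_beverages"] = quantity
    elif spec.label == "bread_butter":
        classes["grains_potatoes_pulses"] = quantity * 0.85
        classes["oils_fats_nuts"] = quantity * 0.15
    else:
        classes["grains_potatoes_pulses"] = quantity
    return dict(
        carbs_g=spec.carbs, fat_g=spec.fat, protein_g=spec.protein, fiber_g=fiber,
        energy_kcal=energy, eaten_quantity_g=quantity,
        standardized_label=spec.label, form=spec.form, **classes,
    )


def _simulate_participant(
    pid: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    standardized_meals: dict[str, StandardizedMealSpec],
) -> dict:
    # order of draws is fixed; side-table couplings never consume trace draws
    age = int(rng.integers(20, 66))
    sex = "F" if rng.random() < 0.5 else "M"
    height = float(rng.normal(170.0, 8.0))
    bmi = float(rng.normal(24.0, 3.0))
    weight = bmi * (height / 100.0) ** 2
    baseline_level = float(rng.normal(cfg.baseline_mean, cfg.baseline_sd))
    z_s = float(rng.normal())
    sensitivity = float(np.exp(cfg.sensitivity_sd * z_s))

    meals: list[dict] = []
    schedule = DEFAULT_STANDARDIZED_SCHEDULE
    for day in range(cfg.n_days):
        day_no = day + 1
        hours = list(MEAL_HOURS[: min(cfg.meals_per_day, 3)])
        jit = list(MEAL_JITTER_H[: len(hours)])
        for _ in range(cfg.meals_per_day - 3):
            hours.append(float(rng.uniform(10.0, 22.0)))
            jit.append(0.0)
        for slot, (h0, j) in enumerate(zip(hours, jit)):
            h = float(np.clip(h0 + rng.normal(0.0, j or 0.25), 0.2, 23.5))
            t = day * MINUTES_PER_DAY + round(h * 60.0)
            if slot == 0 and day_no in cfg.standardized_days:
                label = schedule.get(day_no, "white_bread")
                meal = _standardized_meal(standardized_meals[label])
            else:
                meal = _draw_adlib_meal(rng, cfg)
            meal["t_min"] = float(t)
            # the logged time trails the physiological meal start
            meal["t_phys"] = float(t) - (
                rng.uniform(0.0, cfg.logging_delay_max) if cfg.logging_delay_max > 0 else 0.0
            )
            meals.append(meal)
    meals.sort(key=lambda m: m["t_min"])

    taus, amps, truths = [], [], []
    for meal in meals:
        tau = cfg.liquid_peak_minutes if meal["form"] == "liquid" else cfg.kernel_peak_minutes
        hod = (meal["t_phys"] / 60.0) % 24.0
        truth = meal_response_truth(
            meal["carbs_g"], meal["fat_g"], meal["protein_g"], sensitivity, hod, cfg
        )
        taus.append(tau)
        amps.append(bump_amplitude(truth, tau))
        truths.append(truth)

    grid = np.arange(0.0, cfg.n_days * MINUTES_PER_DAY + cfg.sample_interval / 2, cfg.sample_interval)
    values = render_trace(
        grid,
        np.array([m["t_phys"] for m in meals]),
        np.array(amps),
        np.array(taus),
        baseline_level,
        cfg,
        rng,
    )
    t_obs, y_obs = inject_missingness(
        grid, values, cfg.missing_rate, cfg.long_gap_rate, rng, n_days=cfg.n_days
    )

    # sleep/activity events
    events = []
    for day in range(cfg.n_days):
        s0 = day * MINUTES_PER_DAY + 23 * 60 + rng.normal(0, 30)
        s1 = s0 + 8 * 60 + rng.normal(0, 40)
        events.append(("sleep", s0, s1))
        if rng.random() < 0.5:
            a0 = day * MINUTES_PER_DAY + rng.uniform(17, 19) * 60
            events.append(("activity", a0, a0 + rng.uniform(30, 60)))

    return dict(
        pid=pid, age=age, sex=sex, height=height, weight=weight, bmi=bmi,
        baseline_level=baseline_level, z_s=z_s, sensitivity=sensitivity,
        meals=meals, truths=truths, t_obs=t_obs, y_obs=y_obs, events=events,
    )


def simulate_cohort(
    config: SimulationConfig,
    standardized_meals: dict[str, StandardizedMealSpec] | None = None,
) -> CohortBundle:
    """Generate the full cohort bundle, bit-reproducible for a fixed seed."""
    cfg = config
    specs = standardized_meals or DEFAULT_STANDARDIZED_MEALS
    t0 = pd.Timestamp(cfg.start_date, tz="UTC")
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants + 1)
    side_rng = np.random.default_rng(seqs[-1])

    trace_rows, meal_rows, truth_rows, part_rows, act_rows = [], [], [], [], []
    personal_rows, micro_rows = [], []
    width = max(3, len(str(cfg.n_participants)))
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:0{width}d}"
        rng = np.random.default_rng(seqs[i])
        sim = _simulate_participant(pid, cfg, rng, specs)

        ts = t0 + pd.to_timedelta(sim["t_obs"], unit="m")
        trace_rows.append(
            pd.DataFrame(
                {"participant_id": pid, "timestamp": ts, "glucose_mmol_l": sim["y_obs"]}
            )
        )
        for meal, truth in zip(sim["meals"], sim["truths"]):
            stamp = t0 + pd.Timedelta(minutes=meal["t_min"])
            row = {k: v for k, v in meal.items() if k not in ("t_min", "t_phys", "form")}
            row["participant_id"] = pid
            row["timestamp"] = stamp
            meal_rows.append(row)
            truth_rows.append(
                {"participant_id": pid, "timestamp": stamp, "true_iauc": truth}
            )
        part_rows.append(
            {
                "participant_id": pid,
                "sensitivity": sim["sensitivity"],
                "baseline_level": sim["baseline_level"],
            }
        )
        if side_rng.random() < cfg.personal_coverage:
            personal_rows.append(
                {
                    "participant_id": pid,
                    "age": sim["age"],
                    "sex": sim["sex"],
                    "bmi": sim["bmi"],
                    "weight_kg": sim["weight"],
                    "height_cm": sim["height"],
                }
            )
        if side_rng.random() < cfg.microbiome_coverage:
            me = cfg.microbiome_effect
            eps = side_rng.normal(size=14)
            pcs = eps[4:].copy()
            # optional linear coupling of the first coordinate to log-sensitivity
            pcs[0] = me * sim["z_s"] + np.sqrt(max(0.0, 1 - me**2)) * eps[4]
            row = {
                "participant_id": pid,
                "faith_pd": 15.0 + 3.0 * eps[0],
                "pielou_evenness": float(np.clip(0.8 + 0.08 * eps[1], 0, 1)),
                "observed_features": 250.0 + 60.0 * eps[2],
                "shannon": 6.0 + 0.8 * eps[3],
            }
            row.update({f"unifrac_pc{j + 1}": pcs[j] for j in range(10)})
            micro_rows.append(row)
        if side_rng.random() < cfg.activity_coverage:
            for kind, a, b in sim["events"]:
                act_rows.append(
                    {
                        "participant_id": pid,
                        "kind": kind,
                        "start": (t0 + pd.Timedelta(minutes=float(a))).floor("s"),
                        "end": (t0 + pd.Timedelta(minutes=float(b))).floor("s"),
                    }
                )

    meal_cols = [
        "participant_id", "timestamp", "carbs_g", "fat_g", "protein_g", "fiber_g",
        "energy_kcal", "eaten_quantity_g", *FOOD_CLASSES, "standardized_label",
    ]
    meals = pd.DataFrame(meal_rows)[meal_cols]
    return CohortBundle(
        traces=pd.concat(trace_rows, ignore_index=True),
        meals=meals,
        personal=pd.DataFrame(
            personal_rows,
            columns=["participant_id", "age", "sex", "bmi", "weight_kg", "height_cm"],
        ),
        microbiome=pd.DataFrame(micro_rows),
        activity=pd.DataFrame(act_rows, columns=["participant_id", "kind", "start", "end"]),
        truth_meals=pd.DataFrame(truth_rows),
        truth_participants=pd.DataFrame(part_rows),
        config=cfg,
    )
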