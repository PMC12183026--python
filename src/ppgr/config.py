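"""Configuration models for the simulator, the trainer and the pipeline.

All configuration is pydantic-validated up front; unknown keys are rejected
so a typo in a YAML file fails loudly before any stage runs.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: The six food classes meals are decomposed into (grams per class).
FOOD_CLASSES = (
    "dairy_products_meat_fish_eggs_tofu",
    "vegetables_fruits",
    "sweets_salty_snacks_alcohol",
    "non_alcoholic_beverages",
    "grains_potatoes_pulses",
    "oils_fats_nuts",
)

#: Feature-group labels used throughout: glycemic, diet-compositional,
#: diet-temporal, personal, microbiome, activity.
FEATURE_GROUPS = ("G", "Dc", "Dt", "P", "M", "A")


class StandardizedMealSpec(BaseModel):
    """Composition of one standardized breakfast (~50 g carbohydrates)."""

    model_config = ConfigDict(extra="forbid")

    label: str
    carbs: float = Field(ge=0)
    fat: float = Field(ge=0)
    protein: float = Field(ge=0)
    form: str = "solid"  # "liquid" meals peak earlier


# Approximate compositions: a 50 g glucose drink, plain white bread, and
# white bread with butter (extra ~25 g fat / ~10 g protein).
DEFAULT_STANDARDIZED_MEALS = {
    "glucose_drink": StandardizedMealSpec(
        label="glucose_drink", carbs=50.0, fat=0.0, protein=0.0, form="liquid"
    ),
    "white_bread": StandardizedMealSpec(
        label="white_bread", carbs=50.0, fat=2.0, protein=9.0, form="solid"
    ),
    "bread_butter": StandardizedMealSpec(
        label="bread_butter", carbs=50.0, fat=25.0, protein=10.0, form="solid"
    ),
}

#: Which standardized breakfast is served on which (1-based) study day:
#: bread on days 2-3, bread+butter on days 4-5, glucose drink on days 6-7.
DEFAULT_STANDARDIZED_SCHEDULE = {
    2: "white_bread",
    3: "white_bread",
    4: "bread_butter",
    5: "bread_butter",
    6: "glucose_drink",
    7: "glucose_drink",
}


class SimulationConfig(BaseModel):
    """All knobs of the synthetic-cohort generator.

    The macronutrient effect sizes default to the fitted population effects
    (mmol·min/L per gram): +1.08 carbohydrate, -1.54 fat, -3.27 protein.
    Time units are minutes, glucose is mmol/L.
    """

    model_config = ConfigDict(extra="forbid")

    n_participants: int = Field(default=50, ge=1)
    n_days: int = Field(default=14, ge=2, description="cumulative metrics need a prior day")
    seed: int = Field(default=42, ge=0)

    # Structural meal-response model: iAUC_true =
    #   sensitivity * m(hour) * max(0, beta0 + bC*C + bF*F + bP*P)
    beta0: float = 80.0
    beta_carb: float = Field(default=1.08, gt=0)
    beta_fat: float = -1.54
    beta_protein: float = -3.27
    circadian_gain: float = 0.15
    sensitivity_sd: float = Field(default=0.3, ge=0, description="SD of log individual sensitivity")

    baseline_mean: float = Field(default=5.5, gt=0)
    baseline_sd: float = Field(default=0.4, ge=0)
    baseline_wiggle_sd: float = Field(
        default=0.2, ge=0, description="stationary SD of the slow mean-reverting baseline process"
    )
    noise_sd: float = Field(default=0.25, ge=0)
    quantization: float = Field(default=0.1, ge=0)
    sample_interval: float = Field(default=15.0, gt=0, description="minutes")
    missing_rate: float = Field(default=0.02, ge=0, le=1)
    long_gap_rate: float = Field(default=0.5, ge=0, description="expected long gaps per participant-week")

    meals_per_day: int = Field(default=3, ge=1)
    logging_delay_max: float = Field(
        default=15.0, ge=0,
        description="meals are logged up to this many minutes after the "
        "physiological meal start; the minima-based baseline search exists "
        "to re-anchor the response window at the true excursion onset",
    )
    standardized_days: tuple[int, ...] = tuple(sorted(DEFAULT_STANDARDIZED_SCHEDULE))
    kernel_peak_minutes: float = Field(default=35.0, gt=0)
    liquid_peak_minutes: float = Field(default=25.0, gt=0)

    microbiome_effect: float = Field(default=0.0, ge=-1, le=1)
    activity_effect: float = Field(default=0.0, ge=-1, le=1)
    microbiome_coverage: float = Field(default=0.85, ge=0, le=1)
    activity_coverage: float = Field(default=0.7, ge=0, le=1)
    personal_coverage: float = Field(default=1.0, ge=0, le=1)

    # Ad-lib meal composition (lognormal parameters, grams)
    carb_log_mean: float = 4.382  # ln 80
    carb_log_sd: float = Field(default=0.22, ge=0)
    fat_log_mean: float = 1.609  # ln 5
    fat_log_sd: float = Field(default=0.35, ge=0)
    protein_log_mean: float = 1.946  # ln 7
    protein_log_sd: float = Field(default=0.30, ge=0)
    fiber_log_mean: float = 1.099  # ln 3
    fiber_log_sd: float = Field(default=0.4, ge=0)

    start_date: str = "2023-03-06"

    @model_validator(mode="after")
    def _check_days(self) -> "SimulationConfig":
        bad = [d for d in self.standardized_days if not (1 <= d <= self.n_days)]
        if bad:
            raise ValueError(f"standardized_days outside 1..n_days: {bad}")
        return self


# Hyperparameter ranges reported for the gradient-boosted-tree grid search.
GRID_RANGES = {
    "n_estimators": (1000, 4000),
    "learning_rate": (0.001, 0.01),
    "max_depth": (6, 7, 8),
    "subsample": (0.2, 0.9),
    "colsample_bytree": (0.3, 0.6, 0.9),
}

#: Default search grid bracketing the reported ranges.
DEFAULT_GRID = {
    "n_estimators": [1000, 2000, 3000, 4000],
    "learning_rate": [0.001, 0.005, 0.01],
    "max_depth": [6, 7, 8],
    "subsample": [0.2, 0.5, 0.7, 0.9],
    "colsample_bytree": [0.3, 0.6, 0.9],
}

#: One-point grid (still inside the reported ranges) for quick runs.
REDUCED_GRID = {
    "n_estimators": [1000],
    "learning_rate": [0.01],
    "max_depth": [6],
    "subsample": [0.9],
    "colsample_bytree": [0.9],
}


class TrainingSpec(BaseModel):
    """Grouped-split training protocol for one feature-set combination."""

    model_config = ConfigDict(extra="forbid")

    test_size: float = Field(default=0.2, gt=0, lt=1)
    n_splits: int = Field(default=5, ge=1)
    seed: int = 42
    grid: dict[str, list] = Field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    row_floor: int = Field(default=50, ge=2)
    inner_val_size: float = Field(default=0.2, gt=0, lt=1)

    @model_validator(mode="after")
    def _check_grid(self) -> "TrainingSpec":
        for key, values in self.grid.items():
            if key not in GRID_RANGES:
                raise ValueError(f"unknown grid key: {key}")
            rng = GRID_RANGES[key]
            for v in values:
                if len(rng) == 2:
                    lo, hi = rng
                    if not (lo <= v <= hi):
                        raise ValueError(f"grid value {key}={v} outside range {rng}")
                elif v not in rng:
                    raise ValueError(f"grid value {key}={v} not in {rng}")
        return self


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")

    simulate: bool = True
    features: bool = True
    train: bool = True
    ablate: bool = True
    ols: bool = True
    variance: bool = True
    explain: bool = True
    robustness: bool = False


class RunConfig(BaseModel):
    """Top-level pipeline configuration (one YAML file drives a run)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 42
    out_dir: str = "runs/default"
    format: str = "csv"  # csv | parquet
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    training: TrainingSpec = Field(default_factory=TrainingSpec)
    stages: StageToggles = Field(default_factory=StageToggles)
    combos: Optional[list[str]] = None  # e.g. ["G+Dc+Dt", "Dc", "carbs_only"]
    metrics_in_g: bool = True
    median_impute: bool = False
    robustness_participant_counts: list[int] = Field(default_factory=lambda: [10, 20, 40])
    robustness_train_fractions: list[float] = Field(default_factory=lambda: [0.3, 0.6, 0.9])
    robustness_repeats: int = 2

    @model_validator(mode="after")
    def _check_format(self) -> "RunConfig":
        if self.format not in ("csv", "parquet"):
            raise ValueError(f"format must be csv or parquet, got {self.format}")
        return self
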