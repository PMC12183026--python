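#!/usr/bin/env python
"""Meal-time-stratified models and variance explained per feature group.

Trains the G+Dc+Dt+P model separately on breakfast, lunch and dinner
meals (standardized vs regular breakfasts reported separately) and
quantifies, with plain linear models, the in-sample variance each
feature group explains per meal-time stratum.
"""

import importlib.util
from pathlib import Path

from ppgr.config import REDUCED_GRID, TrainingSpec
from ppgr.modeling import mealtime_models, variance_report

ROOT = Path(__file__).resolve().parents[1] / "results"

_spec = importlib.util.spec_from_file_location(
    "ablation_driver", Path(__file__).parent / "04_ablation.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)


def main() -> None:
    table = _mod.load_table()
    spec = TrainingSpec(grid=REDUCED_GRID, seed=42)

    out = mealtime_models(table, spec)
    print("meal-time-stratified G+Dc+Dt+P models (pooled grouped-CV R):")
    rows = []
    for name, ev in out.items():
        print(f"  {name:24s} R = {ev.pooled_r:.3f}  (n = {ev.n_observations})")
        rows.append({"stratum": name, "pooled_r": ev.pooled_r, "n": ev.n_observations})
    import pandas as pd

    pd.DataFrame(rows).to_csv(ROOT / "mealtime_models.csv", index=False)

    var = variance_report(table)
    var.to_csv(ROOT / "variance_report.csv", index=False)
    print("\nvariance explained (linear in-sample R^2) per group and stratum:")
    print(var.pivot(index="group", columns="stratum", values="r_squared").round(3).to_string())


if __name__ == "__main__":
    main()
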