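#!/usr/bin/env python
"""Replicate studies: does the pipeline behave as designed?

1. Planted-item recovery: how often the 5-method consensus panel contains all
   8 planted items (50 replicates at n=100/100).
2. Panel vs battery: how often the selected panel's pooled CV accuracy beats
   the full battery's, per classifier (50 replicates at n=68/61).
3. Youden cut-off stability: how often the empirical cut-off lands within ±1
   of the closed-form optimum for the planted panel (50 replicates).

Writes results/simulation_studies.json.
"""

import json
from pathlib import Path

from upsit_panel.studies import (
    analytic_youden_optimum,
    panel_vs_battery_study,
    planted_recovery_study,
    youden_stability_study,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1

if __name__ == "__main__":
    RESULTS.mkdir(exist_ok=True)
    rec = planted_recovery_study(n_reps=50, n_pd=100, n_hs=100, seed=SEED)
    print(f"planted recovery: {rec['recovery_rate']:.0%} of {rec['n_reps']} replicates "
          f"(mean panel size {rec['mean_panel_size']:.1f})")

    pvb = panel_vs_battery_study(n_reps=50, seed=SEED + 1)
    print(f"panel >= battery (pooled CV accuracy): "
          f"PLS-DA {pvb['plsda_win_rate']:.0%}, tree {pvb['tree_win_rate']:.0%}")
    print("  note: under this generator all 40 items carry true signal, so a "
          "low-variance PLS-DA gains from the full battery; only the greedy "
          "tree reproduces the published dimension-reduction advantage.")

    yst = youden_stability_study(n_reps=50, seed=SEED + 2)
    print(f"Youden cut-off within ±1 of the analytic optimum "
          f"(t={analytic_youden_optimum()}): {yst['within_one_rate']:.0%}")

    with open(RESULTS / "simulation_studies.json", "w") as fh:
        json.dump({"planted_recovery": rec,
                   "panel_vs_battery": pvb,
                   "youden_stability": yst}, fh, indent=2)
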