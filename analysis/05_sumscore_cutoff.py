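#!/usr/bin/env python
"""Screening cut-off for the panel sum score.

Computes the ROC of the rule "panel score ≤ t ⇒ PD" over all integer
thresholds and picks the Youden-optimal one.  Writes results/roc.csv and
results/cutoff.json.
"""

from pathlib import Path

from upsit_panel.cohort import read_cohort
from upsit_panel.consensus import SelectedPanel
from upsit_panel.cutoff import cutoff_summary, roc_over_cutoffs, sum_score, write_cutoff_summary

RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    cohort = read_cohort(RESULTS / "cohort.csv")
    panel = SelectedPanel.from_json(RESULTS / "panel.json")
    scores = sum_score(cohort, panel)
    roc = roc_over_cutoffs(scores, cohort.y)
    roc.to_csv(RESULTS / "roc.csv")
    summary = cutoff_summary(cohort, panel)
    write_cutoff_summary(summary, RESULTS / "cutoff.json")

    print(roc.table().to_string(index=False))
    print(f"\nchosen rule: {summary['rule']} "
          f"(J={summary['youden_j']:.3f}, sens={summary['sensitivity']:.3f}, "
          f"spec={summary['specificity']:.3f}, AUC={summary['auc']:.3f})")
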