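#!/usr/bin/env python
"""Cross-validated evaluation of PLS-DA and the decision tree on the selected
panel vs the full 40-item battery.

Stratified 10-fold CV, pooled out-of-fold confusion matrices, full diagnostic
metric suite.  Writes results/cv_*.json and the rendered comparison table.
"""

import json
from pathlib import Path

from upsit_panel.classifiers import cross_validate
from upsit_panel.cohort import read_cohort
from upsit_panel.consensus import SelectedPanel
from upsit_panel.report import render_markdown, render_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1

if __name__ == "__main__":
    cohort = read_cohort(RESULTS / "cohort.csv")
    panel = SelectedPanel.from_json(RESULTS / "panel.json")
    n = len(panel.items)

    reports = {}
    for clf, label in (("plsda", "PLS-DA"), ("tree", "DT")):
        for items, tag in ((panel, f"{n}-item"), (None, "40-item")):
            cv = cross_validate(cohort, items=items, classifier=clf, seed=SEED)
            key = f"{label} {tag}"
            reports[key] = cv.report
            with open(RESULTS / f"cv_{clf}_{'panel' if items else 'full'}.json", "w") as fh:
                json.dump(cv.to_dict(), fh, indent=2)
            print(f"{key:>16}: accuracy {cv.report.accuracy:.3f}, AUROC {cv.auroc:.3f}")

    table = render_table(reports)
    table.to_csv(RESULTS / "comparison_table.csv")
    print()
    print(render_markdown(table))
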