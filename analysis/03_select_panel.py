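#!/usr/bin/env python
"""Consensus panel selection: vote over the five top-12 lists.

Items selected by at least 4 of the 5 methods form the abbreviated screening
panel.  Writes results/panel.json and the UpSet-style combination matrix.
"""

from pathlib import Path

from upsit_panel.cohort import read_cohort
from upsit_panel.consensus import combination_matrix
from upsit_panel.pipeline import compute_rankings, consensus_panel
from upsit_panel.simulate import default_spec

RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    cohort = read_cohort(RESULTS / "cohort.csv")
    rankings = compute_rankings(cohort)
    tally, panel = consensus_panel(rankings, k=12, min_votes=4)
    panel.to_json(RESULTS / "panel.json", item_names=cohort.item_names)
    combination_matrix(tally).to_csv(RESULTS / "combination_matrix.csv", index=False)

    print(f"vote distribution (votes: items): {tally.count_distribution()}")
    print(f"panel (>=4 of 5 votes): {panel.items_1based()} ({len(panel.items)} items)")
    planted = {i + 1 for i in default_spec().planted_items}
    print(f"planted items recovered: {planted <= set(panel.items_1based())}")
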