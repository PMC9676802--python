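#!/usr/bin/env python
"""Rank the 40 items by the five discriminability statistics.

Reads results/cohort.csv, writes results/rankings/ranking_<method>.json and
prints each method's top-12 list (1-based item numbers).
"""

from pathlib import Path

from upsit_panel.cohort import read_cohort
from upsit_panel.pipeline import ALL_METHODS, compute_rankings

RESULTS = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    cohort = read_cohort(RESULTS / "cohort.csv")
    out = RESULTS / "rankings"
    out.mkdir(exist_ok=True)
    rankings = compute_rankings(cohort, ALL_METHODS)
    for method, ranking in rankings.items():
        ranking.to_json(out / f"ranking_{method}.json")
        top12 = sorted(i + 1 for i in ranking.order[:12])
        print(f"{method:>8}: top-12 = {top12}")
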