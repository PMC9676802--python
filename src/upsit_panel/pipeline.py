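"""End-to-end pipeline: cohort → 5 rankings → consensus panel → evaluation.

One call runs the whole procedure on a cohort (read from CSV or simulated):
rank items by all five methods, take each method's top-k, vote, select the
≥m-vote panel, cross-validate PLS-DA and the decision tree on both the panel
and the full battery, and derive the Youden sum-score cut-off.  All artifacts
(rankings, panel, combination matrix, CV reports, ROC table, rendered
comparison table, run log) are written to an output directory and returned in
memory.  Every stochastic step is driven by explicit seeds, so a fixed config
yields a byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cohort import CohortMatrix, read_cohort, write_cohort
from .classifiers import DEFAULT_MAX_DEPTH, DEFAULT_MIN_LEAF, DEFAULT_N_COMPONENTS, DEFAULT_N_FOLDS, CvResult, cross_validate
from .consensus import DEFAULT_K, DEFAULT_MIN_VOTES, SelectedPanel, combination_matrix, select_panel, tally_votes, top_k
from .cutoff import cutoff_summary, roc_over_cutoffs, sum_score, write_cutoff_summary
from .multivariate import lda_ranking, logistic_ranking
from .ranking import MethodRanking
from .simulate import default_spec, simulate_cohort
from .univariate import rank_items

ALL_METHODS = ("fisher", "dor", "auc", "logistic", "lda")


@dataclass
class PipelineConfig:
    """Procedural constants of a pipeline run.

    Defaults mirror the published procedure: top-12 lists from 5 methods,
    panel = items with ≥4 votes, stratified 10-fold CV of PLS-DA (2
    components) and a Gini tree.
    """

    k: int = DEFAULT_K
    min_votes: int = DEFAULT_MIN_VOTES
    methods: tuple[str, ...] = ALL_METHODS
    n_folds: int = DEFAULT_N_FOLDS
    n_components: int = DEFAULT_N_COMPONENTS
    max_depth: int = DEFAULT_MAX_DEPTH
    min_leaf: int = DEFAULT_MIN_LEAF
    cv_seed: int = 0
    simulation_seed: int = 0
    cohort_csv: str | None = None    # read this cohort instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)


@dataclass
class PipelineResult:
    cohort: CohortMatrix
    rankings: dict[str, MethodRanking]
    panel: SelectedPanel
    cv_results: dict[str, CvResult]   # keys like "plsda_panel", "tree_full"
    cutoff: dict
    table: "object"                    # pandas DataFrame
    log: dict = field(default_factory=dict)


def compute_rankings(cohort: CohortMatrix, methods=ALL_METHODS) -> dict[str, MethodRanking]:
    rankings: dict[str, MethodRanking] = {}
    for m in methods:
        if m in ("fisher", "dor", "auc"):
            rankings[m] = rank_items(cohort, m)
        elif m == "logistic":
            rankings[m] = logistic_ranking(cohort)
        elif m == "lda":
            rankings[m] = lda_ranking(cohort)
        else:
            raise ValueError(f"unknown ranking method {m!r}")
    return rankings


def consensus_panel(
    rankings: dict[str, MethodRanking], k: int = DEFAULT_K, min_votes: int = DEFAULT_MIN_VOTES
):
    """Top-k vote tally and the ≥min_votes panel from a set of rankings."""
    names = tuple(rankings)
    sets = [top_k(rankings[m], k) for m in names]
    tally = tally_votes(sets, method_names=names, k=k)
    return tally, select_panel(tally, min_votes)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the full procedure; write the artifact bundle if out_dir is given."""
    if config.cohort_csv is not None:
        cohort = read_cohort(config.cohort_csv)
        cohort_source = f"csv:{config.cohort_csv}"
    else:
        spec = default_spec(seed=config.simulation_seed)
        cohort = simulate_cohort(spec)
        cohort_source = f"simulated(default_spec, seed={config.simulation_seed})"

    rankings = compute_rankings(cohort, config.methods)
    tally, panel = consensus_panel(rankings, config.k, config.min_votes)

    cv_results: dict[str, CvResult] = {}
    for clf in ("plsda", "tree"):
        params = (
            {"n_components": config.n_components}
            if clf == "plsda"
            else {"max_depth": config.max_depth, "min_leaf": config.min_leaf}
        )
        cv_results[f"{clf}_panel"] = cross_validate(
            cohort, items=panel, classifier=clf,
            n_folds=config.n_folds, seed=config.cv_seed, **params,
        )
        cv_results[f"{clf}_full"] = cross_validate(
            cohort, items=None, classifier=clf,
            n_folds=config.n_folds, seed=config.cv_seed, **params,
        )

    cut = cutoff_summary(cohort, panel)

    from .report import render_table

    panel_label = f"{len(panel.items)}-item"
    table = render_table({
        f"PLS-DA {panel_label}": cv_results["plsda_panel"].report,
        "PLS-DA 40-item": cv_results["plsda_full"].report,
        f"DT {panel_label}": cv_results["tree_panel"].report,
        "DT 40-item": cv_results["tree_full"].report,
    })

    log = {
        "cohort_source": cohort_source,
        "n_pd": cohort.n_pd,
        "n_hs": cohort.n_hs,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "panel_items_1based": panel.items_1based(),
        "vote_distribution": tally.count_distribution(),
        "declared_defaults": {
            "cv_scheme": "stratified k-fold, shuffled, single repetition, pooled predictions",
            "logistic_penalty": "L2, lambda = 1/(10*n) on summed negative log-likelihood",
            "lda_ridge": "1e-3 * trace(pooled covariance)/p",
            "plsda": f"{config.n_components} components, y in {{0,1}}, threshold 0.5, PD=1",
            "tree": f"gini, max_depth={config.max_depth}, min_leaf={config.min_leaf}, no pruning",
            "tie_breaks": "rankings: ascending item number; tree split: lowest item; leaf tie: PD",
        },
    }

    result = PipelineResult(
        cohort=cohort, rankings=rankings, panel=panel,
        cv_results=cv_results, cutoff=cut, table=table, log=log,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "cohort.csv")
        for m, r in rankings.items():
            r.to_json(out / f"ranking_{m}.json")
        panel.to_json(out / "panel.json", item_names=cohort.item_names)
        combination_matrix(tally).to_csv(out / "combination_matrix.csv", index=False)
        for name, cv in cv_results.items():
            with open(out / f"cv_{name}.json", "w") as fh:
                json.dump(cv.to_dict(), fh, indent=2)
        roc = roc_over_cutoffs(sum_score(cohort, panel), cohort.y)
        roc.to_csv(out / "roc.csv")
        write_cutoff_summary(cut, out / "cutoff.json")
        table.to_csv(out / "comparison_table.csv")
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)

    return result
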