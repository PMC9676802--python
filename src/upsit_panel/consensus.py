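"""Consensus voting over method rankings.

Each ranking method nominates its top-k items; an item's vote tally is the
number of methods nominating it; the consensus panel keeps items with at
least m votes (defaults k=12, M=5 methods, m=4).  The combination matrix —
the tabular form of an UpSet plot — groups items by the exact set of methods
that selected them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .ranking import MethodRanking

DEFAULT_K = 12
DEFAULT_MIN_VOTES = 4


@dataclass(frozen=True)
class VoteTally:
    """Per-item vote counts plus the per-method top-k sets that produced them."""

    counts: dict[int, int]            # 0-based item index -> number of selecting methods
    topk_sets: tuple[frozenset[int], ...]
    method_names: tuple[str, ...]
    k: int

    @property
    def n_methods(self) -> int:
        return len(self.topk_sets)

    def count_distribution(self) -> dict[int, int]:
        """Map vote-count -> number of items with that count (nonzero only)."""
        dist: dict[int, int] = {}
        for c in self.counts.values():
            dist[c] = dist.get(c, 0) + 1
        return dist


@dataclass(frozen=True)
class SelectedPanel:
    """Items with at least ``min_votes`` votes, in ascending item number."""

    items: tuple[int, ...]            # 0-based, sorted ascending
    min_votes: int
    votes: dict[int, int]             # tally restricted to panel members

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(sorted(int(i) for i in self.items)))

    def items_1based(self) -> list[int]:
        return [i + 1 for i in self.items]

    def to_json(self, path, item_names: tuple[str, ...] | None = None) -> None:
        data = {
            "items_1based": self.items_1based(),
            "min_votes": self.min_votes,
            "votes": {str(i + 1): self.votes[i] for i in self.items},
        }
        if item_names is not None:
            data["item_names"] = [item_names[i] for i in self.items]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SelectedPanel":
        with open(path) as fh:
            data = json.load(fh)
        items = tuple(i - 1 for i in data["items_1based"])
        return cls(
            items=items,
            min_votes=data["min_votes"],
            votes={int(k) - 1: v for k, v in data["votes"].items()},
        )


def top_k(ranking: MethodRanking, k: int) -> frozenset[int]:
    """First k items of a ranking (ties already resolved upstream)."""
    if not 1 <= k <= len(ranking.order):
        raise ValueError(f"k={k} out of range [1, {len(ranking.order)}]")
    return frozenset(ranking.order[:k])


def tally_votes(
    topk_sets: list[frozenset[int]],
    method_names: tuple[str, ...] | None = None,
    k: int | None = None,
) -> VoteTally:
    """Count, per item, how many top-k sets contain it."""
    if not topk_sets:
        raise ValueError("at least one top-k set required")
    counts: dict[int, int] = {}
    for s in topk_sets:
        for item in s:
            counts[int(item)] = counts.get(int(item), 0) + 1
    names = method_names or tuple(f"method_{i + 1}" for i in range(len(topk_sets)))
    sizes = {len(s) for s in topk_sets}
    return VoteTally(
        counts=counts,
        topk_sets=tuple(frozenset(s) for s in topk_sets),
        method_names=names,
        k=k if k is not None else max(sizes),
    )


def select_panel(tally: VoteTally, min_votes: int) -> SelectedPanel:
    """Items selected by at least ``min_votes`` of the methods."""
    if not 1 <= min_votes <= tally.n_methods:
        raise ValueError(f"min_votes={min_votes} out of range [1, {tally.n_methods}]")
    items = tuple(sorted(i for i, c in tally.counts.items() if c >= min_votes))
    return SelectedPanel(
        items=items,
        min_votes=min_votes,
        votes={i: tally.counts[i] for i in items},
    )


def combination_matrix(tally: VoteTally) -> pd.DataFrame:
    """UpSet-style table: one row per realized method combination.

    Rows partition the union of all top-k sets: every selected item appears in
    exactly the row of its exact selecting-method subset.  Columns: one 0/1
    indicator per method, the 1-based item list, and the intersection size.
    Per-method set sizes are attached as ``df.attrs['set_sizes']``.
    """
    groups: dict[frozenset[str], list[int]] = {}
    for item in sorted(tally.counts):
        methods = frozenset(
            name for name, s in zip(tally.method_names, tally.topk_sets) if item in s
        )
        groups.setdefault(methods, []).append(item)
    rows = []
    for methods, items in groups.items():
        row = {name: int(name in methods) for name in tally.method_names}
        row["degree"] = len(methods)
        row["n_items"] = len(items)
        row["items_1based"] = ";".join(str(i + 1) for i in items)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["degree", "n_items"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)
    df.attrs["set_sizes"] = {
        name: len(s) for name, s in zip(tally.method_names, tally.topk_sets)
    }
    return df
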