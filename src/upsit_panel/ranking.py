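"""Shared ranking container used by all five item-ranking methods."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

METHODS = ("fisher", "dor", "auc", "logistic", "lda")

# Sort sense per method: fisher ranks by ascending p-value, all others by
# descending score (DOR, AUC, |weight|).
ASCENDING = {"fisher": True, "dor": False, "auc": False, "logistic": False, "lda": False}


@dataclass(frozen=True)
class MethodRanking:
    """Per-item scores of one ranking method plus the induced item order.

    ``order`` lists 0-based item indices from most to least discriminative;
    ties are broken by ascending item index so rankings are deterministic.
    ``direction`` records the sort sense for audit.
    """

    method: str
    scores: np.ndarray
    order: tuple[int, ...]
    direction: str
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        scores = np.asarray(self.scores, dtype=float)
        if sorted(self.order) != list(range(scores.shape[0])):
            raise ValueError("order must be a permutation of all item indices")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "order", tuple(int(i) for i in self.order))

    def to_json(self, path) -> None:
        data = {
            "method": self.method,
            "scores": [float(s) for s in self.scores],
            "order": list(self.order),
            "order_1based": [i + 1 for i in self.order],
            "direction": self.direction,
            "tie_break": "ascending item number",
            "notes": list(self.notes),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MethodRanking":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            method=data["method"],
            scores=np.array(data["scores"], dtype=float),
            order=tuple(data["order"]),
            direction=data["direction"],
            notes=tuple(data.get("notes", ())),
        )


def order_from_scores(scores: np.ndarray, ascending: bool) -> tuple[int, ...]:
    """Stable ordering of item indices by score, ties to the lower index."""
    scores = np.asarray(scores, dtype=float)
    key = scores if ascending else -scores
    return tuple(int(i) for i in np.argsort(key, kind="stable"))
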