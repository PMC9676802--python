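"""Cohort data model: subjects × binary items with a PD/HS class label.

The cohort matrix is the universal input of the pipeline.  Responses are coded
1 = correct odor identification, 0 = incorrect.  All downstream statistics
treat an *incorrect* response as the test-positive state for PD, so that
larger discriminability statistics always mean "more informative item".

Item indices are 0-based internally; user-facing outputs report 1-based item
numbers matching the battery's own numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PD = "PD"
HS = "HS"
VALID_LABELS = (PD, HS)


class CohortFormatError(ValueError):
    """Raised when a cohort CSV does not have the expected columns."""


class CohortValidationError(ValueError):
    """Raised when cohort contents violate the data model."""


def _default_item_names(n_items: int) -> list[str]:
    return [f"item_{i + 1}" for i in range(n_items)]


@dataclass(frozen=True)
class CohortMatrix:
    """Subjects × items binary response matrix with PD/HS labels.

    Attributes
    ----------
    subject_ids : list of unique subject identifiers (row order preserved).
    labels : per-subject class, each ``"PD"`` or ``"HS"``.
    responses : int array of shape (n_subjects, n_items), entries in {0, 1}.
    item_names : per-item display names; defaults to ``item_1 … item_N``.
    """

    subject_ids: tuple[str, ...]
    labels: tuple[str, ...]
    responses: np.ndarray
    item_names: tuple[str, ...] = field(default=())

    def __post_init__(self):
        responses = np.asarray(self.responses, dtype=int)
        if responses.ndim != 2:
            raise CohortValidationError("responses must be a 2-D matrix")
        n_sub, n_items = responses.shape
        if len(self.subject_ids) != n_sub or len(self.labels) != n_sub:
            raise CohortValidationError("subject_ids/labels length must match response rows")
        if len(set(self.subject_ids)) != n_sub:
            raise CohortValidationError("subject identifiers must be unique")
        bad_label = [l for l in self.labels if l not in VALID_LABELS]
        if bad_label:
            raise CohortValidationError(f"labels must be in {VALID_LABELS}; got {bad_label[0]!r}")
        for cls in VALID_LABELS:
            if cls not in self.labels:
                raise CohortValidationError(f"at least one {cls} subject required")
        bad = np.argwhere((responses != 0) & (responses != 1))
        if bad.size:
            r, c = bad[0]
            raise CohortValidationError(
                f"response for subject {self.subject_ids[r]!r}, item {c + 1} "
                f"is {self.responses[r, c]!r}; must be 0 or 1"
            )
        names = tuple(self.item_names) if self.item_names else tuple(_default_item_names(n_items))
        if len(names) != n_items:
            raise CohortValidationError("item_names length must match item count")
        object.__setattr__(self, "responses", responses)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "item_names", names)

    @property
    def n_subjects(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def is_pd(self) -> np.ndarray:
        """Boolean mask of PD subjects (PD coded 1, HS 0 everywhere)."""
        return np.array([l == PD for l in self.labels])

    @property
    def y(self) -> np.ndarray:
        """0/1 class vector, PD = 1."""
        return self.is_pd.astype(int)

    @property
    def n_pd(self) -> int:
        return int(self.is_pd.sum())

    @property
    def n_hs(self) -> int:
        return self.n_subjects - self.n_pd

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortMatrix):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.labels == other.labels
            and self.item_names == other.item_names
            and np.array_equal(self.responses, other.responses)
        )


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 correct/incorrect by class counts for one item.

    ``incorrect_pd + correct_pd`` is the PD class size, likewise for HS.
    """

    incorrect_pd: int
    correct_pd: int
    incorrect_hs: int
    correct_hs: int

    def __post_init__(self):
        for name in ("incorrect_pd", "correct_pd", "incorrect_hs", "correct_hs"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pd(self) -> int:
        return self.incorrect_pd + self.correct_pd

    @property
    def n_hs(self) -> int:
        return self.incorrect_hs + self.correct_hs

    def as_array(self) -> np.ndarray:
        """2×2 array [[incorrect_pd, correct_pd], [incorrect_hs, correct_hs]]."""
        return np.array([[self.incorrect_pd, self.correct_pd],
                         [self.incorrect_hs, self.correct_hs]])


def read_cohort(path) -> CohortMatrix:
    """Read a cohort CSV (columns: subject_id, group, item_1, ..., item_N).

    Raises CohortFormatError for missing/misnamed leading columns and
    CohortValidationError (naming the offending row and column) for invalid
    group labels or non-binary responses.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "subject_id" or cols[1] != "group":
        raise CohortFormatError(
            f"expected header 'subject_id,group,<item columns>'; got {cols[:3]}..."
        )
    item_cols = cols[2:]
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().values)))
        raise CohortValidationError(f"missing value at row {r + 1}, column {cols[c]!r}")
    responses = np.zeros((len(df), len(item_cols)), dtype=int)
    for j, col in enumerate(item_cols):
        vals = df[col].str.strip()
        bad = ~vals.isin(("0", "1"))
        if bad.any():
            r = int(np.argmax(bad.values))
            raise CohortValidationError(
                f"response {vals.iloc[r]!r} at row {r + 1} (subject "
                f"{df['subject_id'].iloc[r]!r}), column {col!r}; must be 0 or 1"
            )
        responses[:, j] = vals.astype(int)
    groups = df["group"].str.strip()
    bad = ~groups.isin(VALID_LABELS)
    if bad.any():
        r = int(np.argmax(bad.values))
        raise CohortValidationError(
            f"group {groups.iloc[r]!r} at row {r + 1}; must be one of {VALID_LABELS}"
        )
    return CohortMatrix(
        subject_ids=tuple(df["subject_id"].str.strip()),
        labels=tuple(groups),
        responses=responses,
        item_names=tuple(item_cols),
    )


def write_cohort(cohort: CohortMatrix, path) -> None:
    """Write a cohort as CSV with stable column order (inverse of read_cohort)."""
    df = pd.DataFrame(cohort.responses, columns=list(cohort.item_names))
    df.insert(0, "group", list(cohort.labels))
    df.insert(0, "subject_id", list(cohort.subject_ids))
    df.to_csv(path, index=False)


def contingency_for_item(cohort: CohortMatrix, item_index: int) -> ContingencyTable:
    """Cross-tabulate one item's correct/incorrect counts by class."""
    if not 0 <= item_index < cohort.n_items:
        raise IndexError(f"item_index {item_index} out of range [0, {cohort.n_items})")
    col = cohort.responses[:, item_index]
    pd_mask = cohort.is_pd
    return ContingencyTable(
        incorrect_pd=int(((col == 0) & pd_mask).sum()),
        correct_pd=int(((col == 1) & pd_mask).sum()),
        incorrect_hs=int(((col == 0) & ~pd_mask).sum()),
        correct_hs=int(((col == 1) & ~pd_mask).sum()),
    )
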