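"""Questionnaire description and response-matrix containers.

A questionnaire is a fixed, ordered list of Likert items on an integer
scale (typically 1 = strong disagreement to 5 = strong agreement).  Items
keyed opposite to their trait ("I see myself as someone who is reserved")
are *reversed* and must be folded onto the common direction before any
scoring, so that a high recoded value always means a socially desirable
answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "QuestionnaireSpec",
    "ResponseMatrix",
    "big_five_10_spec",
    "recode_reversed",
]


@dataclass(frozen=True)
class QuestionnaireSpec:
    """Static description of a Likert questionnaire.

    Parameters
    ----------
    item_ids
        Ordered, unique item identifiers (e.g. ``["Q1", ..., "Q10"]``).
    scale_min, scale_max
        Inclusive integer bounds of the response scale.
    reversed_items
        Items keyed opposite to their trait; recoded as
        ``scale_min + scale_max - value`` before analysis.
    """

    item_ids: tuple[str, ...]
    scale_min: int = 1
    scale_max: int = 5
    reversed_items: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "reversed_items", frozenset(self.reversed_items))
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("item_ids must be unique")
        if not self.item_ids:
            raise ValueError("item_ids must be non-empty")
        if self.scale_min >= self.scale_max:
            raise ValueError(
                f"scale_min ({self.scale_min}) must be < scale_max ({self.scale_max})"
            )
        unknown = self.reversed_items - set(self.item_ids)
        if unknown:
            raise ValueError(f"reversed_items not in item_ids: {sorted(unknown)}")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def scale_values(self) -> np.ndarray:
        """All admissible response values, ascending."""
        return np.arange(self.scale_min, self.scale_max + 1)

    @property
    def n_values(self) -> int:
        return self.scale_max - self.scale_min + 1

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item id: {item_id!r}") from None

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "scale_min": self.scale_min,
            "scale_max": self.scale_max,
            "reversed_items": sorted(self.reversed_items),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuestionnaireSpec":
        return cls(
            item_ids=tuple(d["item_ids"]),
            scale_min=int(d["scale_min"]),
            scale_max=int(d["scale_max"]),
            reversed_items=frozenset(d.get("reversed_items", ())),
        )


def big_five_10_spec() -> QuestionnaireSpec:
    """The 10-item short Big Five inventory on a 1-5 scale.

    Items 2, 3, 5, 7 and 10 (reserved; finds fault; lazy; nervous; few
    artistic interests) are reverse-keyed.
    """
    return QuestionnaireSpec(
        item_ids=tuple(f"Q{i}" for i in range(1, 11)),
        scale_min=1,
        scale_max=5,
        reversed_items=frozenset({"Q2", "Q3", "Q5", "Q7", "Q10"}),
    )


@dataclass
class ResponseMatrix:
    """Integer Likert responses, respondents in rows and items in columns.

    ``recoded`` records whether reversed items have already been folded;
    all scoring operations require a recoded matrix.  Missing values are
    a hard error: term frequencies are undefined on partial rows.
    """

    respondent_ids: tuple[str, ...]
    values: np.ndarray
    spec: QuestionnaireSpec
    recoded: bool = False

    def __post_init__(self) -> None:
        self.respondent_ids = tuple(str(r) for r in self.respondent_ids)
        if len(set(self.respondent_ids)) != len(self.respondent_ids):
            raise ValueError("respondent_ids must be unique")
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape != (len(self.respondent_ids), self.spec.n_items):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.respondent_ids)} respondents x {self.spec.n_items} items"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if np.isnan(np.asarray(values, dtype=float)).any():
                raise ValueError("missing values are not allowed")
            rounded = np.asarray(values, dtype=float)
            if not np.array_equal(rounded, np.round(rounded)):
                raise ValueError("responses must be integers")
            values = rounded.astype(np.int64)
        else:
            values = values.astype(np.int64)
        lo, hi = self.spec.scale_min, self.spec.scale_max
        bad = (values < lo) | (values > hi)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"response {values[r, c]} out of scale [{lo}, {hi}] at "
                f"respondent {self.respondent_ids[r]!r}, item {self.spec.item_ids[c]!r}"
            )
        self.values = values

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    def subset(self, indices: Sequence[int]) -> "ResponseMatrix":
        """Row-subset by positional indices (e.g. a cross-validation fold)."""
        idx = np.asarray(indices, dtype=int)
        return ResponseMatrix(
            respondent_ids=tuple(self.respondent_ids[i] for i in idx),
            values=self.values[idx],
            spec=self.spec,
            recoded=self.recoded,
        )

    def copy(self) -> "ResponseMatrix":
        return replace(self, values=self.values.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        return (
            self.respondent_ids == other.respondent_ids
            and self.spec == other.spec
            and self.recoded == other.recoded
            and np.array_equal(self.values, other.values)
        )


def recode_reversed(matrix: ResponseMatrix) -> ResponseMatrix:
    """Fold reversed items onto the common scale direction.

    For every reversed item, ``value -> scale_min + scale_max - value``;
    other items are untouched.  The transform is an involution, so
    applying it to an already-recoded matrix would silently corrupt the
    data — that is rejected.
    """
    if matrix.recoded:
        raise ValueError("matrix is already recoded; refusing to recode twice")
    values = matrix.values.copy()
    spec = matrix.spec
    for item in spec.reversed_items:
        j = spec.item_index(item)
        values[:, j] = spec.scale_min + spec.scale_max - values[:, j]
    return ResponseMatrix(
        respondent_ids=matrix.respondent_ids,
        values=values,
        spec=spec,
        recoded=True,
    )
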