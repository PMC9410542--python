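"""TF-IDF anomaly scores for questionnaire responses.

The score borrows the term-weighting scheme of information retrieval.
For respondent r and item i with response value v:

* TF(r, i) — how many items in r's own questionnaire carry the value v
  (including item i itself, so TF >= 1).  It captures the respondent's
  response style: repeating one value across many items inflates TF.
* IDF(i, v) = log10(N / n) — how rare the value v is at item i in a
  reference sample of N honest respondents, of whom n gave v.  A
  unanimous value has IDF 0; a value nobody gave gets the maximal
  finite IDF via the continuity correction n <- 0.5.

Their product is high exactly when a respondent leans repeatedly on a
value that honest respondents rarely choose for that item — the
signature of an atypical, possibly faked, response.  Raw response
values can be routed through the same pipeline (``mode="raw"``) as the
distribution-based baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .questionnaire import QuestionnaireSpec, ResponseMatrix

__all__ = [
    "ReferenceModel",
    "ScoreMatrix",
    "term_frequencies",
    "fit_reference",
    "score_matrix",
    "mean_score",
]

ScoreMode = Literal["tfidf", "raw"]


@dataclass
class ReferenceModel:
    """Honest-sample response counts and the derived IDF table.

    ``counts[i, k]`` is the number of reference respondents who gave the
    k-th scale value to item i; rows sum to ``n_respondents``.  IDF is
    recomputed from the counts, which are the single source of truth
    (also across serialization).
    """

    spec: QuestionnaireSpec
    n_respondents: int
    counts: np.ndarray
    smoothing_n0: float = 0.5
    _idf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.spec.n_items, self.spec.n_values):
            raise ValueError(
                f"counts shape {counts.shape} != "
                f"({self.spec.n_items}, {self.spec.n_values})"
            )
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        row_sums = counts.sum(axis=1)
        if not np.all(row_sums == self.n_respondents):
            bad = int(np.argwhere(row_sums != self.n_respondents)[0, 0])
            raise ValueError(
                f"counts for item {self.spec.item_ids[bad]!r} sum to "
                f"{row_sums[bad]}, expected N={self.n_respondents}"
            )
        if not self.smoothing_n0 > 0:
            raise ValueError("smoothing_n0 must be positive")
        self.counts = counts
        n_eff = np.where(counts == 0, self.smoothing_n0, counts)
        self._idf = np.log10(self.n_respondents / n_eff)

    @property
    def idf(self) -> np.ndarray:
        """IDF table, shape (n_items, n_values); log10(N/n) with n0 smoothing."""
        return self._idf

    def idf_of(self, item_id: str, value: int) -> float:
        return float(
            self._idf[self.spec.item_index(item_id), value - self.spec.scale_min]
        )

    def count_of(self, item_id: str, value: int) -> int:
        return int(
            self.counts[self.spec.item_index(item_id), value - self.spec.scale_min]
        )

    # -- serialization: counts are the source of truth, IDF is rebuilt --

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "n_respondents": self.n_respondents,
            "smoothing_n0": self.smoothing_n0,
            "counts": {
                item: {
                    str(v): int(self.counts[i, k])
                    for k, v in enumerate(self.spec.scale_values)
                }
                for i, item in enumerate(self.spec.item_ids)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModel":
        spec = QuestionnaireSpec.from_dict(d["spec"])
        counts = np.zeros((spec.n_items, spec.n_values), dtype=np.int64)
        for i, item in enumerate(spec.item_ids):
            for v_str, n in d["counts"][item].items():
                counts[i, int(v_str) - spec.scale_min] = n
        return cls(
            spec=spec,
            n_respondents=int(d["n_respondents"]),
            counts=counts,
            smoothing_n0=float(d["smoothing_n0"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ScoreMatrix:
    """Per-response scores, respondents x items.

    ``score_mode`` records whether the values are TF-IDF products
    (nonnegative reals) or raw Likert responses (the baseline).
    """

    respondent_ids: tuple[str, ...]
    items: tuple[str, ...]
    scores: np.ndarray
    score_mode: ScoreMode

    def __post_init__(self) -> None:
        self.respondent_ids = tuple(self.respondent_ids)
        self.items = tuple(self.items)
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.respondent_ids), len(self.items)):
            raise ValueError("scores shape does not match ids")
        if self.score_mode == "tfidf" and (scores < 0).any():
            raise ValueError("TF-IDF scores must be nonnegative")
        self.scores = scores

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)


def term_frequencies(row: np.ndarray) -> np.ndarray:
    """Within-row multiplicity of each position's value (TF).

    ``tf[i]`` counts how many entries of ``row`` (including position i)
    equal ``row[i]``; hence ``1 <= tf[i] <= len(row)`` and the
    multiplicities of the distinct values sum to ``len(row)``.
    """
    row = np.asarray(row)
    if row.ndim != 1:
        raise ValueError("row must be 1-D")
    _, inverse, counts = np.unique(row, return_inverse=True, return_counts=True)
    return counts[inverse]


def _tf_table(values: np.ndarray, spec: QuestionnaireSpec) -> np.ndarray:
    """Vectorized TF for every cell of a response matrix."""
    offs = values - spec.scale_min  # (n_resp, n_items) in [0, n_values)
    # occurrences of each scale value within each row
    occ = np.zeros((values.shape[0], spec.n_values), dtype=np.int64)
    np.add.at(occ, (np.arange(values.shape[0])[:, None], offs), 1)
    return np.take_along_axis(occ, offs, axis=1)


def fit_reference(honest: ResponseMatrix) -> ReferenceModel:
    """Tally per-(item, value) response counts over an honest sample.

    The honest matrix must already be recoded and contain at least two
    respondents; the resulting model carries everything needed to score
    new questionnaires (counts, N, the smoothing constant).
    """
    if not honest.recoded:
        raise ValueError("honest matrix must be recoded before fitting")
    if honest.n_respondents < 2:
        raise ValueError(
            f"need at least 2 honest respondents, got {honest.n_respondents}"
        )
    spec = honest.spec
    counts = np.zeros((spec.n_items, spec.n_values), dtype=np.int64)
    offs = honest.values - spec.scale_min
    np.add.at(counts, (np.arange(spec.n_items)[None, :], offs), 1)
    return ReferenceModel(
        spec=spec, n_respondents=honest.n_respondents, counts=counts
    )


def score_matrix(
    matrix: ResponseMatrix, model: ReferenceModel, mode: ScoreMode = "tfidf"
) -> ScoreMatrix:
    """Score every response against the honest reference.

    ``mode="tfidf"`` gives TF(r,i) * IDF(i, value); ``mode="raw"``
    passes the (recoded) response values through unchanged, which is the
    distribution-based baseline scored and thresholded by the identical
    downstream machinery.
    """
    if not matrix.recoded:
        raise ValueError("matrix must be recoded before scoring")
    if matrix.spec != model.spec:
        raise ValueError("matrix spec does not match reference model spec")
    if mode == "raw":
        scores = matrix.values.astype(float)
    elif mode == "tfidf":
        tf = _tf_table(matrix.values, matrix.spec)
        item_idx = np.arange(matrix.spec.n_items)[None, :]
        idf_cells = model.idf[item_idx, matrix.values - matrix.spec.scale_min]
        scores = tf * idf_cells
    else:
        raise ValueError(f"unknown score mode: {mode!r}")
    return ScoreMatrix(
        respondent_ids=matrix.respondent_ids,
        items=matrix.spec.item_ids,
        scores=scores,
        score_mode=mode,
    )


def mean_score(scores: ScoreMatrix) -> np.ndarray:
    """Per-respondent arithmetic mean across items.

    The questionnaire-level summary used to flag fakers: honest
    respondents concentrate at low mean TF-IDF, fakers above it.
    """
    return scores.scores.mean(axis=1)
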