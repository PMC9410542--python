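"""Percentile-threshold calibration and faked-item / faker detection.

Detection is a one-sided outlier test per item: a response is flagged
as faked when its score strictly exceeds a cutoff taken as a fixed
percentile of the honest score distribution for that item.  One shared
percentile is tuned by K-fold cross-validated grid search (maximising
F1 by default), then materialised as per-item cutoffs on the full
honest sample.  A respondent is flagged as a faker when their mean
score across items exceeds a questionnaire-level cutoff (3.0 for
TF-IDF on the 10-item Big Five).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .evaluation import EvaluationReport, confusion, evaluate_detection, metrics
from .questionnaire import ResponseMatrix
from .scoring import ScoreMatrix, ScoreMode, fit_reference, mean_score, score_matrix

__all__ = [
    "ThresholdSet",
    "DetectionResult",
    "DEFAULT_PERCENTILE_GRID",
    "percentile_cutoffs",
    "detect_items",
    "detect_fakers",
    "kfold_split",
    "calibrate",
]

#: Percentile candidates searched during calibration.  The grid brackets
#: the 75th percentile that works well on the Big Five data and extends
#: to 100 so that fully separable data can reach a zero-false-positive
#: threshold.
DEFAULT_PERCENTILE_GRID: tuple[float, ...] = (
    50.0, 60.0, 70.0, 75.0, 80.0, 85.0, 90.0, 95.0, 99.0, 100.0,
)

#: Mean-TF-IDF cutoff above which a respondent is flagged as a faker.
DEFAULT_FAKER_CUTOFF: float = 3.0


@dataclass
class ThresholdSet:
    """Per-item decision cutoffs generated by one shared percentile.

    ``cutoffs[item]`` is the ``percentile``-th percentile (linear
    interpolation between order statistics) of the honest score sample
    for that item, in the units of ``score_mode``.
    """

    percentile: float
    cutoffs: dict[str, float]
    score_mode: ScoreMode
    objective: str = "f1"
    grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError("percentile must be in [0, 100]")

    def cutoff_vector(self, items: Sequence[str]) -> np.ndarray:
        return np.array([self.cutoffs[i] for i in items])

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "cutoffs": self.cutoffs,
            "score_mode": self.score_mode,
            "objective": self.objective,
            "grid": list(self.grid) if self.grid is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(
            percentile=float(d["percentile"]),
            cutoffs={k: float(v) for k, v in d["cutoffs"].items()},
            score_mode=d["score_mode"],
            objective=d.get("objective", "f1"),
            grid=tuple(d["grid"]) if d.get("grid") is not None else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class DetectionResult:
    """Item-level flags plus the respondent-level mean-score summary."""

    respondent_ids: tuple[str, ...]
    items: tuple[str, ...]
    item_flags: np.ndarray  # bool, respondents x items
    respondent_mean: np.ndarray
    faker_flags: np.ndarray
    faker_cutoff: float


def percentile_cutoffs(
    honest_scores: ScoreMatrix, percentile: float
) -> ThresholdSet:
    """Per-item cutoffs at one percentile of the honest score sample.

    Uses linear interpolation between closest order statistics — the
    score distributions are heavily tied, so the convention matters and
    is fixed here.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    if honest_scores.n_respondents < 2:
        raise ValueError("need at least 2 honest respondents for cutoffs")
    cuts = np.percentile(honest_scores.scores, percentile, axis=0)
    return ThresholdSet(
        percentile=float(percentile),
        cutoffs={item: float(c) for item, c in zip(honest_scores.items, cuts)},
        score_mode=honest_scores.score_mode,
    )


def detect_items(
    scores: ScoreMatrix,
    thresholds: ThresholdSet,
    faker_cutoff: float = DEFAULT_FAKER_CUTOFF,
) -> DetectionResult:
    """Flag each response whose score strictly exceeds its item cutoff.

    Ties at the cutoff count as honest.  The per-respondent mean score
    and the faker flag (mean > ``faker_cutoff``) are filled in as well.
    """
    if scores.score_mode != thresholds.score_mode:
        raise ValueError(
            f"score mode mismatch: scores are {scores.score_mode!r}, "
            f"thresholds are {thresholds.score_mode!r}"
        )
    cut = thresholds.cutoff_vector(scores.items)
    flags = scores.scores > cut[None, :]
    means = mean_score(scores)
    return DetectionResult(
        respondent_ids=scores.respondent_ids,
        items=scores.items,
        item_flags=flags,
        respondent_mean=means,
        faker_flags=detect_fakers(means, faker_cutoff),
        faker_cutoff=faker_cutoff,
    )


def detect_fakers(
    respondent_mean: np.ndarray, cutoff: float = DEFAULT_FAKER_CUTOFF
) -> np.ndarray:
    """Respondent-level rule: faker iff mean score strictly above cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    return np.asarray(respondent_mean) > cutoff


def kfold_split(
    n_respondents: int, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled K-fold partition of respondent indices.

    Validation sets are disjoint, cover all respondents, and differ in
    size by at most one; the split is deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_respondents < k:
        raise ValueError(f"k={k} exceeds number of respondents ({n_respondents})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train.copy(), val.copy()) for train, val in kf.split(np.arange(n_respondents))
    ]


def _objective_value(pred: np.ndarray, truth: np.ndarray, objective: str) -> float:
    c = confusion(pred, truth)
    _, precision, recall, f1 = metrics(c, warn=False)
    return {"f1": f1, "precision": precision}[objective]


def calibrate(
    honest: ResponseMatrix,
    faked: ResponseMatrix,
    truth: np.ndarray,
    mode: ScoreMode = "tfidf",
    objective: str = "f1",
    percentile_grid: Sequence[float] = DEFAULT_PERCENTILE_GRID,
    k: int = 10,
    seed: int = 0,
    faker_cutoff: float = DEFAULT_FAKER_CUTOFF,
) -> tuple[ThresholdSet, EvaluationReport]:
    """Cross-validated grid search for the detection percentile.

    For each fold, a reference model and per-item percentile cutoffs are
    fitted on the training-fold honest respondents only; every grid
    percentile is then scored (by ``objective``) on the validation-fold
    faked responses against their item-level truth labels.  The
    percentile with the best mean objective across folds wins, ties
    going to the lower percentile; the returned ThresholdSet is refitted
    on the full honest sample at that percentile.

    The fold unit is the respondent: both conditions of a person travel
    together, so no respondent's honest rows help set the cutoffs used
    to judge their own faked rows.  The returned report pools the
    out-of-fold predictions at the winning percentile.
    """
    if honest.spec != faked.spec:
        raise ValueError("honest and faked matrices must share a spec")
    if honest.n_respondents != faked.n_respondents:
        raise ValueError("honest and faked matrices must be paired (same respondents)")
    truth = np.asarray(truth, dtype=bool)
    if truth.shape != faked.values.shape:
        raise ValueError("truth table shape must match the faked matrix")
    if objective not in ("f1", "precision"):
        raise ValueError(f"unknown objective: {objective!r}")
    grid = [float(p) for p in percentile_grid]
    if not grid:
        raise ValueError("percentile_grid must be non-empty")
    if any(not 0.0 <= p <= 100.0 for p in grid):
        raise ValueError("grid percentiles must be in [0, 100]")
    if not truth.any():
        raise ValueError("truth has no faked responses; recall is uncomputable")

    grid = sorted(grid)
    folds = kfold_split(honest.n_respondents, k=k, seed=seed)
    fold_obj = np.zeros((len(folds), len(grid)))
    fold_flags: list[list[np.ndarray]] = [[] for _ in grid]
    val_order: list[np.ndarray] = []

    for f, (train, val) in enumerate(folds):
        model = fit_reference(honest.subset(train))
        train_scores = score_matrix(honest.subset(train), model, mode)
        val_scores = score_matrix(faked.subset(val), model, mode)
        truth_val = truth[val]
        val_order.append(val)
        for g, p in enumerate(grid):
            ts = percentile_cutoffs(train_scores, p)
            flags = val_scores.scores > ts.cutoff_vector(val_scores.items)[None, :]
            fold_obj[f, g] = _objective_value(flags, truth_val, objective)
            fold_flags[g].append(flags)

    mean_obj = fold_obj.mean(axis=0)
    best = int(np.argmax(mean_obj))  # first max = lowest percentile on ties
    winner = grid[best]

    # out-of-fold predictions at the winning percentile, in original order
    order = np.concatenate(val_order)
    pooled = np.vstack(fold_flags[best])
    oof_flags = np.empty_like(pooled)
    oof_flags[order] = pooled

    report = evaluate_detection(
        predicted=oof_flags,
        truth=truth,
        items=honest.spec.item_ids,
        extra={
            "cv_percentile": winner,
            "cv_mean_objective": float(mean_obj[best]),
            "objective": objective,
            "score_mode": mode,
            "k": k,
            "seed": seed,
        },
    )

    model_all = fit_reference(honest)
    final = percentile_cutoffs(score_matrix(honest, model_all, mode), winner)
    final.objective = objective
    final.grid = tuple(grid)
    return final, report
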