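"""Ground truth, confusion metrics, KL separability and case reports.

Because every study participant answered the questionnaire twice — once
faking, once honestly — item-level ground truth is simply inequality of
the paired responses: a faked cell is one the respondent changed.
Detection quality is then the standard 2x2 tally with faked as the
positive class.  Accuracy for a respondent is the fraction of their
items classified correctly (e.g. 8/10); dataset accuracy is the mean of
per-respondent accuracies, while precision/recall/F1 pool all cells.

Separability of honest vs dishonest score distributions is measured
per item with the Kullback-Leibler divergence KL(dishonest || honest)
on epsilon-smoothed histograms (natural log).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .questionnaire import ResponseMatrix
from .scoring import ReferenceModel, score_matrix

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "truth_labels",
    "confusion",
    "metrics",
    "kl_divergence",
    "per_item_kl",
    "odds_to_probability",
    "empirical_odds",
    "summarize_by_faked_count",
    "evaluate_detection",
    "single_case_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally over (respondent, item) cells; positives = faked."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvaluationReport:
    """Dataset-level detection quality summary."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_item_accuracy: dict[str, float]
    per_faked_count: dict[int, tuple[int, float]]
    kl: dict[str, tuple[float, float]] | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_item_accuracy": self.per_item_accuracy,
            "per_faked_count": {
                str(k): {"respondents": n, "mean_accuracy": a}
                for k, (n, a) in self.per_faked_count.items()
            },
            "kl": (
                {item: {"raw": r, "tfidf": t} for item, (r, t) in self.kl.items()}
                if self.kl is not None
                else None
            ),
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            accuracy=d["accuracy"],
            precision=d["precision"],
            recall=d["recall"],
            f1=d["f1"],
            per_item_accuracy=dict(d["per_item_accuracy"]),
            per_faked_count={
                int(k): (v["respondents"], v["mean_accuracy"])
                for k, v in d["per_faked_count"].items()
            },
            kl=(
                {item: (v["raw"], v["tfidf"]) for item, v in d["kl"].items()}
                if d.get("kl") is not None
                else None
            ),
            extra=dict(d.get("extra", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EvaluationReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_text(self) -> str:
        lines = [
            f"accuracy   {self.accuracy:.4f}",
            f"precision  {self.precision:.4f}",
            f"recall     {self.recall:.4f}",
            f"F1         {self.f1:.4f}",
            "",
            "per-item accuracy:",
        ]
        for item, acc in self.per_item_accuracy.items():
            lines.append(f"  {item:<6s} {acc:.4f}")
        lines.append("")
        lines.append("respondents by number of faked items:")
        for count in sorted(self.per_faked_count):
            n, acc = self.per_faked_count[count]
            lines.append(f"  {count:>2d} faked: {n:>4d} respondents, mean accuracy {acc:.4f}")
        return "\n".join(lines) + "\n"


def truth_labels(honest: ResponseMatrix, dishonest: ResponseMatrix) -> np.ndarray:
    """Item-level faking labels from a paired honest/dishonest pair.

    A cell is labelled faked iff the dishonest response differs from the
    honest response the same respondent gave to the same item.
    """
    if honest.respondent_ids != dishonest.respondent_ids:
        raise ValueError("honest and dishonest matrices list different respondents")
    if honest.spec != dishonest.spec:
        raise ValueError("honest and dishonest matrices have different specs")
    if not (honest.recoded and dishonest.recoded):
        raise ValueError("both matrices must be recoded")
    return honest.values != dishonest.values


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally the 2x2 table; faked is the positive class."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape}, truth {truth.shape}"
        )
    return ConfusionCounts(
        tp=int((predicted & truth).sum()),
        fp=int((predicted & ~truth).sum()),
        fn=int((~predicted & truth).sum()),
        tn=int((~predicted & ~truth).sum()),
    )


def metrics(
    c: ConfusionCounts, warn: bool = True
) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) from a confusion tally.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
    mean.  Any 0/0 is reported as 0 (optionally with a warning) so that
    threshold sweeps over degenerate extremes never crash.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    accuracy = (c.tp + c.tn) / c.total

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            if warn:
                warnings.warn(
                    f"{name} is 0/0; reporting 0", RuntimeWarning, stacklevel=3
                )
            return 0.0
        return num / den

    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


def kl_divergence(
    sample_p: np.ndarray,
    sample_q: np.ndarray,
    bins: int | Sequence[float] = 10,
    epsilon: float = 1e-6,
) -> float:
    """KL(p || q) between two samples via smoothed histograms.

    ``bins`` is either a bin count (equal-width bins spanning the pooled
    sample range — for continuous scores) or explicit edges (for raw
    integer responses, one bin per scale value).  Both histograms get
    additive epsilon smoothing and renormalisation, so the result is
    finite and >= 0 up to smoothing error; natural log.
    """
    p = np.asarray(sample_p, dtype=float)
    q = np.asarray(sample_q, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("samples must be nonempty")
    edges = np.histogram_bin_edges(np.concatenate([p, q]), bins=bins)
    hp, _ = np.histogram(p, bins=edges)
    hq, _ = np.histogram(q, bins=edges)
    fp = hp / hp.sum() + epsilon
    fq = hq / hq.sum() + epsilon
    fp /= fp.sum()
    fq /= fq.sum()
    return float(np.sum(fp * np.log(fp / fq)))


def per_item_kl(
    honest: ResponseMatrix,
    dishonest: ResponseMatrix,
    model: ReferenceModel,
    bins: int = 10,
    epsilon: float = 1e-6,
) -> dict[str, tuple[float, float]]:
    """Per-item KL(dishonest || honest) for raw scores and TF-IDF.

    Raw mode bins are the integer scale values; TF-IDF mode uses
    ``bins`` equal-width bins over the pooled score range of each item.
    Large TF-IDF KL with small raw KL is the signature that the TF-IDF
    representation separates honest from dishonest responses where raw
    values overlap.
    """
    spec = honest.spec
    raw_edges = np.arange(spec.scale_min - 0.5, spec.scale_max + 1.0)
    h_tfidf = score_matrix(honest, model, "tfidf").scores
    d_tfidf = score_matrix(dishonest, model, "tfidf").scores
    out: dict[str, tuple[float, float]] = {}
    for j, item in enumerate(spec.item_ids):
        kl_raw = kl_divergence(
            dishonest.values[:, j], honest.values[:, j], bins=raw_edges, epsilon=epsilon
        )
        kl_tf = kl_divergence(
            d_tfidf[:, j], h_tfidf[:, j], bins=bins, epsilon=epsilon
        )
        out[item] = (kl_raw, kl_tf)
    return out


def odds_to_probability(odds: float) -> float:
    """Convert odds of faking to a probability, as a percentage.

    Odds of 3.8 fakers per honest respondent above a cutoff correspond
    to a 100 * 3.8 / 4.8 = 79.2% probability that a flagged respondent
    is a faker.
    """
    if odds <= 0:
        raise ValueError("odds must be positive")
    return 100.0 * odds / (1.0 + odds)


def empirical_odds(
    honest_means: np.ndarray, faked_means: np.ndarray, cutoff: float = 3.0
) -> float:
    """Fakers per honest respondent among mean scores above a cutoff.

    Returns ``math.inf`` when no honest respondent exceeds the cutoff
    (every flagged respondent is a faker).
    """
    honest_means = np.asarray(honest_means, dtype=float)
    faked_means = np.asarray(faked_means, dtype=float)
    if honest_means.size == 0 or faked_means.size == 0:
        raise ValueError("mean vectors must be nonempty")
    n_honest = int((honest_means > cutoff).sum())
    n_faked = int((faked_means > cutoff).sum())
    if n_honest == 0:
        return math.inf
    return n_faked / n_honest


def summarize_by_faked_count(
    truth: np.ndarray, predicted: np.ndarray
) -> dict[int, tuple[int, float]]:
    """Group respondents by how many items they faked.

    Returns {number of faked items: (respondent count, mean per-
    respondent accuracy)}; group counts partition the respondents.
    """
    truth = np.asarray(truth, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have the same shape")
    n_items = truth.shape[1]
    faked_counts = truth.sum(axis=1)
    resp_acc = (predicted == truth).sum(axis=1) / n_items
    out: dict[int, tuple[int, float]] = {}
    for count in np.unique(faked_counts):
        mask = faked_counts == count
        out[int(count)] = (int(mask.sum()), float(resp_acc[mask].mean()))
    return out


def evaluate_detection(
    predicted: np.ndarray,
    truth: np.ndarray,
    items: Sequence[str],
    kl: dict[str, tuple[float, float]] | None = None,
    extra: dict | None = None,
) -> EvaluationReport:
    """Full detection report from item-level flags and truth labels."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same shape")
    c = confusion(predicted, truth)
    _, precision, recall, f1 = metrics(c, warn=False)
    # dataset accuracy = mean of per-respondent accuracies
    resp_acc = (predicted == truth).mean(axis=1)
    per_item = {
        item: float((predicted[:, j] == truth[:, j]).mean())
        for j, item in enumerate(items)
    }
    return EvaluationReport(
        accuracy=float(resp_acc.mean()),
        precision=precision,
        recall=recall,
        f1=f1,
        per_item_accuracy=per_item,
        per_faked_count=summarize_by_faked_count(truth, predicted),
        kl=kl,
        extra=extra or {},
    )


def single_case_report(
    respondent_id: str,
    items: Sequence[str],
    scores: np.ndarray,
    cutoffs: np.ndarray,
    truth_row: np.ndarray | None = None,
) -> str:
    """Plain-text per-item listing for one respondent.

    One line per item: score, cutoff, flag, and — when a paired honest
    administration is available — the true faked/honest label.
    """
    scores = np.asarray(scores, dtype=float)
    cutoffs = np.asarray(cutoffs, dtype=float)
    lines = [f"respondent {respondent_id}"]
    header = f"{'item':<6s} {'score':>8s} {'cutoff':>8s} {'flag':>6s}"
    if truth_row is not None:
        header += f" {'truth':>6s}"
    lines.append(header)
    n_correct = 0
    for j, item in enumerate(items):
        flagged = scores[j] > cutoffs[j]
        line = (
            f"{item:<6s} {scores[j]:>8.3f} {cutoffs[j]:>8.3f} "
            f"{'FAKED' if flagged else 'ok':>6s}"
        )
        if truth_row is not None:
            line += f" {'faked' if truth_row[j] else 'honest':>6s}"
            n_correct += int(flagged == bool(truth_row[j]))
        lines.append(line)
    lines.append(f"mean score: {scores.mean():.3f}")
    if truth_row is not None:
        lines.append(f"accuracy: {n_correct}/{len(items)}")
    return "\n".join(lines) + "\n"
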