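"""Paired honest/faked Likert response simulator.

The generator reproduces the statistical structure observed in three
instructed-faking studies on the 10-item Big Five questionnaire, one
faking context per study:

* ``CC``   — child-custody litigation (fake to look like a good parent),
* ``JIS``  — job interview, sales-manager position,
* ``JIHO`` — job interview, humanitarian organisation.

Honest responses are drawn independently per (respondent, item) from a
discretised truncated normal whose first two moments match the honest
sample mean and SD reported for that item.  Faking is modelled per item
as: with the item's empirical faking probability the respondent alters
the response; an alteration moves toward the desirable end of the scale
with probability ``increase_share`` (fakers occasionally move the
"wrong" way), and the new value is uniform over the admissible values
strictly beyond the current one in the chosen direction.  All values
are on the *recoded* scale (reversed items already folded), matching
how the empirical tables were computed.

The simulator is the test bed for the whole pipeline: it provides
paired matrices plus exact item-level truth labels without any data
download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .questionnaire import QuestionnaireSpec, ResponseMatrix, big_five_10_spec

__all__ = [
    "ItemParams",
    "FakingParams",
    "CONTEXTS",
    "context_params",
    "fit_discrete_distribution",
    "generate_honest",
    "generate_faked_pair",
    "generate_dataset",
    "generate_roster",
    "apply_quality_filter",
]


@dataclass(frozen=True)
class ItemParams:
    """Per-item generator targets, on the recoded scale.

    ``honest_mean``/``honest_sd`` are the moments of the honest response
    distribution; ``faking_prob`` is the probability that a faker alters
    the response to this item.
    """

    item_id: str
    honest_mean: float
    honest_sd: float
    faking_prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.faking_prob <= 1.0:
            raise ValueError("faking_prob must be in [0, 1]")
        if self.honest_sd < 0:
            raise ValueError("honest_sd must be nonnegative")


@dataclass(frozen=True)
class FakingParams:
    """Direction mix of alterations.

    ``increase_share`` is the probability that an altered response moves
    toward scale_max (the socially desirable direction under faking-good
    instructions); the empirical pooled share of increases among changes
    is about 0.78, with 13-15% of changes moving the opposite way.
    """

    increase_share: float = 0.78

    def __post_init__(self) -> None:
        if not 0.0 <= self.increase_share <= 1.0:
            raise ValueError("increase_share must be in [0, 1]")


def _items(rows: list[tuple[float, float, float]]) -> tuple[ItemParams, ...]:
    return tuple(
        ItemParams(f"Q{i + 1}", m, s, p) for i, (m, s, p) in enumerate(rows)
    )


# Empirical honest means / SDs and per-item faking probabilities for the
# three contexts, plus each study's alteration direction mix
# (increase_share = %increased / (%increased + %decreased)) and the
# enrolment bookkeeping (records collected, records failing the
# instruction-comprehension check).
CONTEXTS: dict[str, dict] = {
    "CC": {
        "items": _items(
            [
                (3.87, 0.90, 0.60),
                (2.43, 0.96, 0.48),
                (2.96, 0.99, 0.72),
                (3.42, 0.97, 0.52),
                (3.17, 1.22, 0.76),
                (4.48, 0.68, 0.39),
                (2.94, 1.22, 0.74),
                (3.01, 1.09, 0.77),
                (3.54, 1.10, 0.66),
                (3.32, 1.25, 0.59),
            ]
        ),
        "faking": FakingParams(increase_share=48 / (48 + 14)),
        "n_enrolled": 258,
        "n_failed_check": 37,
    },
    "JIS": {
        "items": _items(
            [
                (3.67, 0.97, 0.67),
                (2.44, 1.09, 0.61),
                (2.95, 1.04, 0.77),
                (3.42, 1.06, 0.62),
                (3.21, 1.20, 0.74),
                (4.47, 0.77, 0.39),
                (2.74, 1.18, 0.79),
                (2.92, 1.14, 0.80),
                (3.63, 1.04, 0.70),
                (3.45, 1.26, 0.62),
            ]
        ),
        "faking": FakingParams(increase_share=52 / (52 + 15)),
        "n_enrolled": 287,
        "n_failed_check": 44,
    },
    "JIHO": {
        "items": _items(
            [
                (3.77, 0.95, 0.64),
                (2.38, 1.04, 0.63),
                (3.00, 1.11, 0.71),
                (3.55, 0.96, 0.65),
                (3.21, 1.25, 0.73),
                (4.49, 0.71, 0.38),
                (2.81, 1.16, 0.77),
                (3.00, 1.18, 0.76),
                (3.56, 1.10, 0.66),
                (3.42, 1.26, 0.54),
            ]
        ),
        "faking": FakingParams(increase_share=52 / (52 + 13)),
        "n_enrolled": 272,
        "n_failed_check": 42,
    },
}


def context_params(context: str) -> dict:
    try:
        return CONTEXTS[context]
    except KeyError:
        raise ValueError(
            f"unknown context {context!r}; expected one of {sorted(CONTEXTS)}"
        ) from None


def _discrete_probs(
    mu: float, sigma: float, values: np.ndarray
) -> np.ndarray:
    """Normal(mu, sigma) mass discretised onto integer scale values.

    Bin k covers [v_k - 0.5, v_k + 0.5); the outer bins absorb the
    tails, which truncates the distribution to the scale.
    """
    inner = values[:-1] + 0.5
    edges = np.concatenate([[-np.inf], inner, [np.inf]])
    cdf = stats.norm.cdf(edges, loc=mu, scale=sigma)
    p = np.diff(cdf)
    return p / p.sum()


def _moments(p: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    m = float(np.dot(p, values))
    var = float(np.dot(p, (values - m) ** 2))
    return m, float(np.sqrt(var))


def fit_discrete_distribution(
    mean: float,
    sd: float,
    spec: QuestionnaireSpec,
    tol: float = 0.02,
) -> np.ndarray:
    """Probability vector over scale values matching a target mean and SD.

    Solves for the (mu, sigma) of a normal whose discretisation onto the
    integer scale reproduces the targets within ``tol``; ``sd=0``
    degenerates to a point mass at the nearest scale value.  Raises if
    the targets are infeasible on the scale (the maximal variance of any
    distribution on [lo, hi] with the given mean is (mean-lo)(hi-mean);
    the minimal SD for a non-integer mean is that of the two-point mix
    of the neighbouring values).
    """
    lo, hi = spec.scale_min, spec.scale_max
    if not lo <= mean <= hi:
        raise ValueError(f"mean {mean} outside scale [{lo}, {hi}]")
    values = spec.scale_values.astype(float)
    if sd == 0:
        p = np.zeros(spec.n_values)
        p[int(np.argmin(np.abs(values - mean)))] = 1.0
        return p

    sd_max = float(np.sqrt((mean - lo) * (hi - mean)))
    frac = mean - np.floor(mean)
    sd_min = float(np.sqrt(frac * (1 - frac)))
    if sd > sd_max + tol or sd < sd_min - tol:
        raise ValueError(
            f"targets (mean={mean}, sd={sd}) infeasible on scale [{lo}, {hi}]; "
            f"feasible SD range is [{sd_min:.3f}, {sd_max:.3f}]"
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        m, s = _moments(_discrete_probs(theta[0], theta[1], values), values)
        return np.array([m - mean, s - sd])

    sol = optimize.least_squares(
        residual,
        x0=np.array([mean, max(sd, 0.05)]),
        bounds=([lo - 4.0, 1e-4], [hi + 4.0, 4.0 * (hi - lo)]),
    )
    p = _discrete_probs(sol.x[0], sol.x[1], values)
    m, s = _moments(p, values)
    if abs(m - mean) > tol or abs(s - sd) > tol:
        raise ValueError(
            f"could not match targets (mean={mean}, sd={sd}) within {tol}: "
            f"achieved mean={m:.4f}, sd={s:.4f}"
        )
    return p


def generate_honest(
    n: int,
    params: list[ItemParams] | tuple[ItemParams, ...],
    spec: QuestionnaireSpec | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Draw n honest questionnaires, independent across cells.

    Each item's responses come from its moment-matched discrete
    distribution; values are on the recoded scale, so the matrix is
    flagged ``recoded=True``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec is None:
        spec = big_five_10_spec()
    if len(params) != spec.n_items:
        raise ValueError("one ItemParams per item required")
    rng = np.random.default_rng(seed)
    cols = []
    for ip in params:
        p = fit_discrete_distribution(ip.honest_mean, ip.honest_sd, spec)
        cols.append(rng.choice(spec.scale_values, size=n, p=p))
    return ResponseMatrix(
        respondent_ids=tuple(f"R{i + 1}" for i in range(n)),
        values=np.column_stack(cols),
        spec=spec,
        recoded=True,
    )


def generate_faked_pair(
    honest: ResponseMatrix,
    params: list[ItemParams] | tuple[ItemParams, ...],
    fp: FakingParams | None = None,
    seed: int = 0,
) -> tuple[ResponseMatrix, np.ndarray]:
    """Derive the dishonest administration of each honest questionnaire.

    Per cell: with probability ``faking_prob`` the response is altered.
    An alteration moves up (toward scale_max) with probability
    ``increase_share``, else down; the new value is uniform over the
    values strictly beyond the current one in that direction, and if
    the chosen direction has no room (value already at that bound) the
    other direction is used.  The truth table marks exactly the cells
    that changed.
    """
    if not honest.recoded:
        raise ValueError("honest matrix must be recoded")
    if fp is None:
        fp = FakingParams()
    spec = honest.spec
    if len(params) != spec.n_items:
        raise ValueError("one ItemParams per item required")
    rng = np.random.default_rng(seed)
    v = honest.values
    n, m = v.shape
    probs = np.array([ip.faking_prob for ip in params])

    change = rng.random((n, m)) < probs[None, :]
    go_up = rng.random((n, m)) < fp.increase_share
    u = rng.random((n, m))

    room_up = spec.scale_max - v
    room_dn = v - spec.scale_min
    # fall back to the only available direction at the scale bounds
    up = np.where(room_up == 0, False, np.where(room_dn == 0, True, go_up))

    step_up = 1 + np.floor(u * room_up).astype(np.int64)
    step_dn = 1 + np.floor(u * room_dn).astype(np.int64)
    np.clip(step_up, None, np.maximum(room_up, 1), out=step_up)
    np.clip(step_dn, None, np.maximum(room_dn, 1), out=step_dn)

    new_values = np.where(up, v + step_up, v - step_dn)
    faked_values = np.where(change, new_values, v)

    faked = ResponseMatrix(
        respondent_ids=honest.respondent_ids,
        values=faked_values,
        spec=spec,
        recoded=True,
    )
    truth = faked.values != honest.values
    return faked, truth


def generate_dataset(
    context: str, n: int, seed: int = 0
) -> tuple[ResponseMatrix, ResponseMatrix, np.ndarray]:
    """Paired (honest, dishonest, truth) dataset for one faking context."""
    cfg = context_params(context)
    spec = big_five_10_spec()
    s_honest, s_faked = _child_seeds(seed, 2)
    honest = generate_honest(n, cfg["items"], spec, seed=s_honest)
    dishonest, truth = generate_faked_pair(
        honest, cfg["items"], cfg["faking"], seed=s_faked
    )
    return honest, dishonest, truth


def _child_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(k)]


def generate_roster(context: str, seed: int = 0) -> pd.DataFrame:
    """Enrolment roster with the instruction-comprehension check outcome.

    Reproduces each study's record counts: of the enrolled participants
    a fixed number answered the comprehension question incorrectly and
    must be excluded before analysis.
    """
    cfg = context_params(context)
    n, n_fail = cfg["n_enrolled"], cfg["n_failed_check"]
    rng = np.random.default_rng(seed)
    passed = np.ones(n, dtype=bool)
    passed[rng.choice(n, size=n_fail, replace=False)] = False
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1}" for i in range(n)],
            "context": context,
            "passed_check": passed,
        }
    )


def apply_quality_filter(roster: pd.DataFrame) -> pd.DataFrame:
    """Drop participants who failed the comprehension check."""
    if "passed_check" not in roster.columns:
        raise ValueError("roster must have a 'passed_check' column")
    return roster[roster["passed_check"]].reset_index(drop=True)
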