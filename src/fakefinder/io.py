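"""Reading and writing response matrices, truth tables and score files.

The on-disk format is a strict CSV/TSV dialect: UTF-8, a header row of
item ids, and a first column named ``respondent_id``.  Validation is
loud — a missing cell, an out-of-range value or a duplicate respondent
id is an error naming the offending coordinates, never a silent
coercion.  TSV is selected by file extension.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .questionnaire import QuestionnaireSpec, ResponseMatrix, recode_reversed
from .scoring import ScoreMatrix, ScoreMode

__all__ = [
    "read_responses",
    "write_responses",
    "read_truth",
    "write_truth",
    "read_scores",
    "write_scores",
    "write_flags",
]

ID_COLUMN = "respondent_id"


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_table(path: str | Path, spec: QuestionnaireSpec) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path), dtype={0: str})
    if df.empty:
        raise ValueError(f"{path}: empty response matrix")
    if df.columns[0] != ID_COLUMN:
        raise ValueError(
            f"{path}: first column must be {ID_COLUMN!r}, got {df.columns[0]!r}"
        )
    header = tuple(df.columns[1:])
    if header != spec.item_ids:
        raise ValueError(
            f"{path}: header items {list(header)} do not match "
            f"spec items {list(spec.item_ids)}"
        )
    ids = df[ID_COLUMN].tolist()
    dup = pd.Series(ids)[pd.Series(ids).duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate respondent id {dup.iloc[0]!r}")
    body = df.iloc[:, 1:]
    for r, c in zip(*np.where(body.isna())):
        raise ValueError(
            f"{path}: missing value at respondent {ids[r]!r}, "
            f"item {spec.item_ids[c]!r}"
        )
    return df


def read_responses(
    path: str | Path,
    spec: QuestionnaireSpec,
    already_recoded: bool = False,
) -> ResponseMatrix:
    """Load a response CSV/TSV and validate it against the spec.

    Reversed items are recoded on load; pass ``already_recoded=True``
    for files that store recoded values (e.g. simulator output), which
    skips the fold.  The returned matrix is always in recoded form.
    """
    path = Path(path)
    df = _read_table(path, spec)
    ids = df[ID_COLUMN].tolist()
    body = df.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for c, item in enumerate(spec.item_ids):
        col = pd.to_numeric(body.iloc[:, c], errors="coerce")
        if col.isna().any():
            r = int(np.where(col.isna())[0][0])
            raise ValueError(
                f"{path}: non-numeric value {body.iloc[r, c]!r} at "
                f"respondent {ids[r]!r}, item {item!r}"
            )
        values[:, c] = col.to_numpy()
    if not np.array_equal(values, np.round(values)):
        r, c = np.argwhere(values != np.round(values))[0]
        raise ValueError(
            f"{path}: non-integer value {values[r, c]} at respondent "
            f"{ids[r]!r}, item {spec.item_ids[c]!r}"
        )
    values = values.astype(np.int64)
    lo, hi = spec.scale_min, spec.scale_max
    bad = (values < lo) | (values > hi)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: value {values[r, c]} out of scale [{lo}, {hi}] at "
            f"respondent {ids[r]!r}, item {spec.item_ids[c]!r}"
        )
    matrix = ResponseMatrix(
        respondent_ids=tuple(ids),
        values=values,
        spec=spec,
        recoded=already_recoded,
    )
    if not already_recoded:
        matrix = recode_reversed(matrix)
    return matrix


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix; values are stored exactly as held in memory."""
    df = pd.DataFrame(matrix.values, columns=list(matrix.spec.item_ids))
    df.insert(0, ID_COLUMN, list(matrix.respondent_ids))
    df.to_csv(path, sep=_sep(path), index=False)


def read_truth(
    path: str | Path, spec: QuestionnaireSpec
) -> tuple[tuple[str, ...], np.ndarray]:
    """Load a 0/1 truth table; returns (respondent ids, boolean array)."""
    df = _read_table(path, spec)
    values = df.iloc[:, 1:].to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: truth cells must be 0 or 1")
    return tuple(df[ID_COLUMN].tolist()), values.astype(bool)


def write_truth(
    respondent_ids: tuple[str, ...],
    truth: np.ndarray,
    spec: QuestionnaireSpec,
    path: str | Path,
) -> None:
    df = pd.DataFrame(
        np.asarray(truth, dtype=int), columns=list(spec.item_ids)
    )
    df.insert(0, ID_COLUMN, list(respondent_ids))
    df.to_csv(path, sep=_sep(path), index=False)


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    df = pd.DataFrame(scores.scores, columns=list(scores.items))
    df.insert(0, ID_COLUMN, list(scores.respondent_ids))
    df.to_csv(path, sep=_sep(path), index=False, float_format="%.10g")


def read_scores(path: str | Path, score_mode: ScoreMode) -> ScoreMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(path), dtype={0: str})
    if df.empty or df.columns[0] != ID_COLUMN:
        raise ValueError(f"{path}: not a score file (expected {ID_COLUMN!r} column)")
    return ScoreMatrix(
        respondent_ids=tuple(df[ID_COLUMN].tolist()),
        items=tuple(df.columns[1:]),
        scores=df.iloc[:, 1:].to_numpy(dtype=float),
        score_mode=score_mode,
    )


def write_flags(
    respondent_ids: tuple[str, ...],
    items: tuple[str, ...],
    flags: np.ndarray,
    path: str | Path,
) -> None:
    df = pd.DataFrame(np.asarray(flags, dtype=int), columns=list(items))
    df.insert(0, ID_COLUMN, list(respondent_ids))
    df.to_csv(path, sep=_sep(path), index=False)
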