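import math

import numpy as np
import pytest
from hypothesis import settings

from fakefinder import (
    QuestionnaireSpec,
    ResponseMatrix,
    big_five_10_spec,
    generate_dataset,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def naive_tfidf_scores(
    values: np.ndarray,
    counts: np.ndarray,
    n_ref: int,
    scale_min: int = 1,
    smoothing: float = 0.5,
) -> np.ndarray:
    """Independent nested-loop TF-IDF oracle (no vectorization)."""
    n_r, n_i = values.shape
    out = np.zeros((n_r, n_i))
    for r in range(n_r):
        for i in range(n_i):
            v = values[r, i]
            tf = sum(1 for j in range(n_i) if values[r, j] == v)
            n = counts[i, v - scale_min]
            out[r, i] = tf * math.log10(n_ref / (n if n > 0 else smoothing))
    return out


@pytest.fixture
def spec5() -> QuestionnaireSpec:
    """Small 5-item questionnaire, no reversed items."""
    return QuestionnaireSpec(item_ids=("Q1", "Q2", "Q3", "Q4", "Q5"))


@pytest.fixture
def big_five() -> QuestionnaireSpec:
    return big_five_10_spec()


@pytest.fixture
def tiny_honest(spec5) -> ResponseMatrix:
    """Four honest respondents; item Q1 carries the values [5, 5, 4, 2]."""
    values = np.array(
        [
            [5, 3, 1, 2, 4],
            [5, 3, 2, 2, 4],
            [4, 3, 3, 2, 4],
            [2, 3, 4, 2, 4],
        ]
    )
    return ResponseMatrix(
        respondent_ids=("A", "B", "C", "D"),
        values=values,
        spec=spec5,
        recoded=True,
    )


@pytest.fixture(scope="session")
def cc_dataset():
    """One mid-size CC synthetic dataset shared across tests."""
    return generate_dataset("CC", 400, seed=11)
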