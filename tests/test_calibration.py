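import numpy as np
import pytest

from fakefinder import (
    DEFAULT_PERCENTILE_GRID,
    QuestionnaireSpec,
    ResponseMatrix,
    ScoreMatrix,
    ThresholdSet,
    calibrate,
    confusion,
    detect_fakers,
    detect_items,
    fit_reference,
    kfold_split,
    metrics,
    percentile_cutoffs,
    score_matrix,
)


def _score_fixture(items, column_scores, mode="tfidf"):
    """ScoreMatrix with one shared score column repeated per item."""
    col = np.asarray(column_scores, dtype=float)
    scores = np.tile(col[:, None], (1, len(items)))
    ids = tuple(f"R{i}" for i in range(len(col)))
    return ScoreMatrix(ids, tuple(items), scores, mode)


class TestPercentileCutoffs:
    @pytest.mark.parametrize(
        "percentile,expected", [(100, 3.0), (0, 0.0), (75, 2.25), (50, 1.5)]
    )
    def test_linear_interpolation_on_0123(self, percentile, expected):
        s = _score_fixture(["Q1"], [0, 1, 2, 3])
        ts = percentile_cutoffs(s, percentile)
        assert ts.cutoffs["Q1"] == pytest.approx(expected)
        assert ts.percentile == percentile

    def test_one_cutoff_per_item(self):
        s = _score_fixture(["Q1", "Q2", "Q3"], [0, 1, 2, 3])
        ts = percentile_cutoffs(s, 75)
        assert set(ts.cutoffs) == {"Q1", "Q2", "Q3"}

    def test_rejects_single_respondent(self):
        s = _score_fixture(["Q1"], [1.0])
        with pytest.raises(ValueError, match="at least 2"):
            percentile_cutoffs(s, 75)

    def test_serialization_roundtrip(self, tmp_path):
        ts = percentile_cutoffs(_score_fixture(["Q1", "Q2"], [0, 1, 2, 3]), 75)
        ts.grid = (50.0, 75.0)
        path = tmp_path / "thresholds.json"
        ts.save(path)
        loaded = ThresholdSet.load(path)
        assert loaded.percentile == ts.percentile
        assert loaded.cutoffs == ts.cutoffs
        assert loaded.score_mode == ts.score_mode
        assert loaded.grid == ts.grid


class TestDetectItems:
    def test_flags_scores_strictly_above_cutoff(self):
        s = _score_fixture(["Q1"], [9.11, 2.0, 1.99])
        ts = ThresholdSet(percentile=75, cutoffs={"Q1": 2.0}, score_mode="tfidf")
        result = detect_items(s, ts)
        assert result.item_flags[:, 0].tolist() == [True, False, False]

    def test_all_zero_scores_never_flagged(self):
        s = _score_fixture(["Q1", "Q2"], [0.0, 0.0])
        ts = ThresholdSet(percentile=75, cutoffs={"Q1": 0.5, "Q2": 1.0}, score_mode="tfidf")
        assert not detect_items(s, ts).item_flags.any()

    def test_mode_mismatch_is_an_error(self):
        s = _score_fixture(["Q1"], [1.0, 2.0], mode="raw")
        ts = ThresholdSet(percentile=75, cutoffs={"Q1": 1.0}, score_mode="tfidf")
        with pytest.raises(ValueError, match="mode"):
            detect_items(s, ts)

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random((30, 4)) * 8
        items = ("Q1", "Q2", "Q3", "Q4")
        s = ScoreMatrix(tuple(f"R{i}" for i in range(30)), items, scores, "tfidf")
        cut = {q: float(c) for q, c in zip(items, rng.random(4) * 8)}
        ts = ThresholdSet(percentile=75, cutoffs=cut, score_mode="tfidf")
        base = detect_items(s, ts).item_flags

        f = lambda x: np.exp(x / 4) + x  # strictly increasing
        s2 = ScoreMatrix(s.respondent_ids, items, f(scores), "tfidf")
        ts2 = ThresholdSet(
            percentile=75,
            cutoffs={q: float(f(np.array(c))) for q, c in cut.items()},
            score_mode="tfidf",
        )
        assert np.array_equal(detect_items(s2, ts2).item_flags, base)


class TestDetectFakers:
    @pytest.mark.parametrize(
        "mean,expected", [(3.5, True), (3.0, False), (0.0, False)]
    )
    def test_strict_mean_rule(self, mean, expected):
        assert detect_fakers(np.array([mean]), cutoff=3.0)[0] == expected

    def test_rejects_negative_cutoff(self):
        with pytest.raises(ValueError):
            detect_fakers(np.array([1.0]), cutoff=-1)


class TestKfoldSplit:
    def test_partitions_into_equal_folds(self):
        folds = kfold_split(20, k=10, seed=1)
        vals = [set(v.tolist()) for _, v in folds]
        assert all(len(v) == 2 for v in vals)
        assert set().union(*vals) == set(range(20))
        # validation sets pairwise disjoint
        assert sum(len(v) for v in vals) == 20

    def test_deterministic_given_seed(self):
        a = kfold_split(23, k=10, seed=7)
        b = kfold_split(23, k=10, seed=7)
        for (ta, va), (tb, vb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(va, vb)

    def test_uneven_sizes_differ_by_at_most_one(self):
        folds = kfold_split(23, k=10, seed=0)
        sizes = sorted(len(v) for _, v in folds)
        assert set(sizes) <= {2, 3}
        assert sum(sizes) == 23

    def test_k_larger_than_n_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_split(5, k=10, seed=0)


def _separable_dataset():
    """Faked cells use a value honest respondents never pick.

    Honest rows cycle over values {1, 2, 3}; the dishonest copy sets the
    first five items to 5, so every faked cell's TF-IDF (5 x the maximal
    smoothed IDF) dwarfs every honest score.
    """
    spec = QuestionnaireSpec(item_ids=tuple(f"Q{i}" for i in range(1, 11)))
    n = 40
    values = np.empty((n, 10), dtype=int)
    for r in range(n):
        for j in range(10):
            values[r, j] = (r + j) % 3 + 1
    ids = tuple(f"R{i}" for i in range(n))
    honest = ResponseMatrix(ids, values, spec, recoded=True)
    faked_values = values.copy()
    faked_values[:, :5] = 5
    faked = ResponseMatrix(ids, faked_values, spec, recoded=True)
    truth = faked_values != values
    return honest, faked, truth


class TestCalibrate:
    def test_separable_data_reaches_perfect_f1(self):
        honest, faked, truth = _separable_dataset()
        # sanity: full-sample faked scores strictly dominate honest ones
        model = fit_reference(honest)
        h = score_matrix(honest, model).scores
        f = score_matrix(faked, model).scores
        assert f[truth].min() > h.max()

        ts, report = calibrate(honest, faked, truth, k=5, seed=3)
        assert report.extra["cv_mean_objective"] == pytest.approx(1.0)
        assert report.f1 == pytest.approx(1.0)

    def test_percentile_zero_flags_everything_above_minimum(self, cc_dataset):
        honest, faked, truth = cc_dataset
        model = fit_reference(honest)
        honest_scores = score_matrix(honest, model, "raw")
        ts = percentile_cutoffs(honest_scores, 0)
        col_min = honest_scores.scores.min(axis=0)
        assert np.array_equal(ts.cutoff_vector(honest_scores.items), col_min)
        faked_scores = score_matrix(faked, model, "raw")
        flagged = detect_items(faked_scores, ts).item_flags
        # everything strictly above the per-item honest minimum is flagged
        assert np.array_equal(flagged, faked_scores.scores > col_min[None, :])
        c = confusion(flagged, truth)
        _, precision, recall, _ = metrics(c, warn=False)
        above = faked_scores.scores > col_min[None, :]
        assert recall == pytest.approx(truth[above].sum() / truth.sum())
        # precision equals the faked base rate among the flagged cells
        assert precision == pytest.approx(truth[flagged].sum() / flagged.sum())

    def test_selected_percentile_matches_exhaustive_oracle(self):
        from fakefinder import generate_dataset

        honest, faked, truth = generate_dataset("CC", 400, seed=7)
        grid = list(DEFAULT_PERCENTILE_GRID)
        k, seed = 10, 7
        ts, _ = calibrate(
            honest, faked, truth, percentile_grid=grid, k=k, seed=seed
        )

        # independent re-evaluation: plain loops over folds and grid
        folds = kfold_split(honest.n_respondents, k=k, seed=seed)
        grid_sorted = sorted(grid)
        mean_obj = []
        for p in grid_sorted:
            vals = []
            for train, val in folds:
                model = fit_reference(honest.subset(train))
                tr_scores = score_matrix(honest.subset(train), model)
                cutoffs = percentile_cutoffs(tr_scores, p)
                va_scores = score_matrix(faked.subset(val), model)
                flags = va_scores.scores > cutoffs.cutoff_vector(va_scores.items)
                _, _, _, f1 = metrics(confusion(flags, truth[val]), warn=False)
                vals.append(f1)
            mean_obj.append(np.mean(vals))
        oracle_winner = grid_sorted[int(np.argmax(mean_obj))]
        assert ts.percentile == oracle_winner

    def test_reproducible_given_seed(self, cc_dataset):
        honest, faked, truth = cc_dataset
        ts1, r1 = calibrate(honest, faked, truth, k=5, seed=9)
        ts2, r2 = calibrate(honest, faked, truth, k=5, seed=9)
        assert ts1.percentile == ts2.percentile
        assert ts1.cutoffs == ts2.cutoffs
        assert r1.f1 == r2.f1

    def test_raw_mode_runs_same_path(self, cc_dataset):
        honest, faked, truth = cc_dataset
        ts, report = calibrate(honest, faked, truth, mode="raw", k=5, seed=2)
        assert ts.score_mode == "raw"
        assert 0 <= report.f1 <= 1

    def test_empty_grid_is_an_error(self, cc_dataset):
        honest, faked, truth = cc_dataset
        with pytest.raises(ValueError, match="grid"):
            calibrate(honest, faked, truth, percentile_grid=[])

    def test_truth_without_positives_is_an_error(self, cc_dataset):
        honest, faked, truth = cc_dataset
        with pytest.raises(ValueError, match="no faked"):
            calibrate(honest, faked, np.zeros_like(truth))

    def test_lower_percentile_never_reduces_recall(self, cc_dataset):
        honest, faked, truth = cc_dataset
        model = fit_reference(honest)
        honest_scores = score_matrix(honest, model)
        faked_scores = score_matrix(faked, model)
        recalls, n_unflagged = [], []
        for p in sorted(DEFAULT_PERCENTILE_GRID, reverse=True):
            ts = percentile_cutoffs(honest_scores, p)
            flags = detect_items(faked_scores, ts).item_flags
            _, _, recall, _ = metrics(confusion(flags, truth), warn=False)
            recalls.append(recall)
            n_unflagged.append((~flags).sum())
        assert all(b >= a - 1e-12 for a, b in zip(recalls, recalls[1:]))
        assert all(b <= a for a, b in zip(n_unflagged, n_unflagged[1:]))
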