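"""CV splitting, one-vs-rest runs, weighted AUC, experiment bookkeeping."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from wristhar.classification import (
    CVSplit,
    RunResult,
    SkippedRun,
    WindowDataset,
    make_subject_folds,
    make_window_folds,
    run_experiment,
    train_eval_binary,
    weighted_auc,
)
from tests.conftest import cheap_model_factory


class ScoreFirstFeature:
    """Stub model: the first feature column is the positive-class score."""

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.clip(X[:, 0], 0.0, 1.0)
        return np.column_stack([1 - p, p])


class AlwaysNegative:
    """Majority-class stub: constant zero probability."""

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return np.column_stack([np.ones(len(X)), np.zeros(len(X))])


def _dataset(n_per_subject=40, subjects=("a", "b", "c"), pos_rate=0.5, seed=0):
    """Dataset whose first feature equals the positive indicator + noise."""
    rng = np.random.default_rng(seed)
    X, labels, subj = [], [], []
    for s in subjects:
        y = (rng.random(n_per_subject) < pos_rate).astype(int)
        x0 = y * 0.8 + 0.1  # perfectly ranked scores
        X.append(np.column_stack([x0, rng.normal(size=n_per_subject)]))
        labels.extend(np.where(y == 1, "target", "other"))
        subj.extend([s] * n_per_subject)
    return WindowDataset(
        window_size=60,
        X=np.vstack(X),
        labels=np.asarray(labels),
        subjects=np.asarray(subj),
    )


class TestMakeSubjectFolds:
    def test_34_subjects_three_folds_sizes(self):
        split = make_subject_folds([f"S{i}" for i in range(34)], 3, 0)
        sizes = sorted(len(split.subjects_in(f)) for f in range(3))
        assert sizes == [11, 11, 12]

    def test_one_subject_per_fold(self):
        split = make_subject_folds(["a", "b", "c"], 3, 1)
        assert sorted(len(split.subjects_in(f)) for f in range(3)) == [1, 1, 1]

    def test_deterministic(self):
        ids = [f"S{i}" for i in range(10)]
        assert make_subject_folds(ids, 3, 7).fold_of == make_subject_folds(ids, 3, 7).fold_of

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            make_subject_folds(["a", "b"], 3, 0)

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(3, 60), k=st.integers(2, 5), seed=st.integers(0, 1000))
    def test_partition_properties(self, n, k, seed):
        if n < k:
            return
        ids = [f"S{i}" for i in range(n)]
        split = make_subject_folds(ids, k, seed)
        folds = [split.subjects_in(f) for f in range(k)]
        # every subject in exactly one fold
        assert sorted(s for f in folds for s in f) == sorted(ids)
        # folds as equal as possible
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        # train/test disjoint for every held-out fold
        for f in range(k):
            train, test = split.train_test_subjects(f)
            assert not train & test
            assert train | test == set(ids)


class TestTrainEvalBinary:
    def test_perfect_separation_auc_one(self):
        ds = _dataset()
        split = make_subject_folds(["a", "b", "c"], 3, 0)
        res = train_eval_binary(
            ds, "target", split, 0, 0, seed=0, model_factory=lambda s: ScoreFirstFeature()
        )
        assert res.auc == 1.0
        assert res.n_test_windows == 40

    def test_label_independent_scores_auc_half(self):
        # permutation oracle: scores independent of labels -> AUC ~ 0.5
        rng = np.random.default_rng(3)
        n = 4000
        y = (rng.random(n) < 0.3).astype(int)
        scores = rng.normal(size=n)  # independent of y
        assert roc_auc_score(y, scores) == pytest.approx(0.5, abs=0.03)

    def test_majority_class_dissociation(self):
        # 95%-negative test set: accuracy 0.95 but AUC exactly 0.5
        ds = _dataset(n_per_subject=200, pos_rate=0.05, seed=5)
        split = make_subject_folds(["a", "b", "c"], 3, 0)
        res = train_eval_binary(
            ds, "target", split, 0, 0, seed=0, model_factory=lambda s: AlwaysNegative()
        )
        assert res.accuracy >= 0.9
        assert res.accuracy == pytest.approx(1 - res.n_test_positives / res.n_test_windows)
        assert res.auc == 0.5

    def test_no_training_positives_skipped(self):
        ds = _dataset()
        ds.labels[ds.subjects != "a"] = "other"  # positives only in subject a
        split = CVSplit(fold_of={"a": 1, "b": 0, "c": 2}, k=3)
        with pytest.raises(SkippedRun):
            # test fold 1 = {a}: training subjects {b, c} carry no positives
            train_eval_binary(ds, "target", split, 1, 0, seed=0,
                              model_factory=lambda s: ScoreFirstFeature())

    def test_subject_disjointness_enforced_by_split(self):
        ds = _dataset()
        split = make_subject_folds(["a", "b", "c"], 3, 0)
        for fold in range(3):
            train, test = split.train_test_subjects(fold)
            assert not train & test

    def test_real_model_learns_separable_data(self):
        ds = _dataset(n_per_subject=80)
        split = make_subject_folds(["a", "b", "c"], 3, 0)
        res = train_eval_binary(ds, "target", split, 0, 0, seed=0,
                                model_factory=cheap_model_factory)
        assert res.auc > 0.95


class TestWeightedAuc:
    def test_hand_arithmetic(self):
        runs = [
            _run(auc=0.8, n_pos=10),
            _run(auc=0.6, n_pos=30),
        ]
        assert weighted_auc(runs) == pytest.approx(0.65)

    def test_single_run_identity(self):
        assert weighted_auc([_run(auc=0.73, n_pos=5)]) == pytest.approx(0.73)

    def test_equal_weights_arithmetic_mean(self):
        runs = [_run(auc=a, n_pos=7) for a in (0.5, 0.7, 0.9)]
        assert weighted_auc(runs) == pytest.approx(0.7)

    def test_zero_weights_error(self):
        with pytest.raises(ValueError):
            weighted_auc([_run(auc=0.8, n_pos=0)])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            weighted_auc([])


def _run(auc: float, n_pos: int) -> RunResult:
    return RunResult(
        activity="x", window_size=60, fold=0, iteration=0,
        auc=auc, accuracy=0.9, n_test_windows=100, n_test_positives=n_pos,
    )


class TestRunExperiment:
    def test_product_count_2x1x3x1(self):
        ds = _dataset(n_per_subject=60, seed=2)
        results, runs = run_experiment(
            {60: ds}, ["target", "other"], k=3, iterations=1, seed=0,
            model_factory=lambda s: ScoreFirstFeature(),
        )
        assert len(runs) == 6  # 2 activities x 1 window size x 3 folds x 1 iteration
        assert len(results) == 2

    def test_rows_sorted_by_auc_descending(self):
        ds = _dataset(n_per_subject=60, seed=2)
        results, _ = run_experiment(
            {60: ds}, ["target", "other"], k=3, iterations=1, seed=0,
            model_factory=lambda s: ScoreFirstFeature(),
        )
        aucs = [r.auc for r in results]
        assert aucs == sorted(aucs, reverse=True)

    def test_bout_counts_percentages(self):
        ds = _dataset(n_per_subject=60, seed=2)
        results, _ = run_experiment(
            {60: ds}, ["target"], k=3, iterations=1, seed=0,
            bout_counts={"target": 25, "other": 75},
            model_factory=lambda s: ScoreFirstFeature(),
        )
        assert results[0].num_pos == 25
        assert results[0].pos_pct == pytest.approx(25.0)

    def test_missing_window_size_store(self):
        with pytest.raises(ValueError):
            run_experiment({}, ["target"], k=3, iterations=1, seed=0)

    def test_window_folds_partition(self):
        folds = make_window_folds(100, 3, 0)
        assert set(folds) == {0, 1, 2}
        assert len(folds) == 100


class TestAucInvariance:
    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_transform_preserves_auc(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(50) < 0.4).astype(int)
        if y.sum() in (0, 50):
            return
        s = rng.normal(size=50)
        base = roc_auc_score(y, s)
        for f in (np.exp, np.tanh, lambda v: v**3, lambda v: 5 * v + 2):
            assert roc_auc_score(y, f(s)) == pytest.approx(base, abs=1e-12)
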