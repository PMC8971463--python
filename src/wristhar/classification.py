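"""One-vs-rest gradient-boosted classification under subject-independent CV.

For each activity and window size, a binary model (positive = that
activity, negative = every other activity; background windows are
excluded upstream) is trained on two of three subject folds and
evaluated on the held-out fold.  "Iterations" repeat each fold's run
with a different model seed and a different inner subject-level
validation split, giving k x iterations runs per activity per window
size (60 with the defaults).  Run AUCs are aggregated per activity with
weights equal to the test fold's positive window count.

The model backend is pluggable (any estimator with fit/predict_proba);
the default is scikit-learn's histogram gradient boosting at default
hyperparameters with balanced class weights to counter the strong
class imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import accuracy_score, roc_auc_score

logger = logging.getLogger(__name__)

DEFAULT_FOLDS = 3
DEFAULT_ITERATIONS = 20

#: Fraction of training subjects held out as the inner validation split.
VALIDATION_FRACTION = 0.25

ModelFactory = Callable[[int], object]


def default_model_factory(seed: int) -> HistGradientBoostingClassifier:
    """Gradient-boosted trees, default hyperparameters, imbalance reweighting."""
    return HistGradientBoostingClassifier(class_weight="balanced", random_state=seed)


@dataclass(frozen=True)
class CVSplit:
    """Subject-to-fold assignment for k-fold subject-independent CV."""

    fold_of: Mapping[str, int]
    k: int

    def __post_init__(self) -> None:
        folds = set(self.fold_of.values())
        if not folds.issubset(range(self.k)):
            raise ValueError("fold indices out of range")

    def subjects_in(self, fold: int) -> tuple[str, ...]:
        return tuple(s for s, f in self.fold_of.items() if f == fold)

    def train_test_subjects(self, test_fold: int) -> tuple[set[str], set[str]]:
        test = {s for s, f in self.fold_of.items() if f == test_fold}
        train = {s for s in self.fold_of if s not in test}
        return train, test


@dataclass(frozen=True)
class RunResult:
    """AUC + accuracy of one train/test run."""

    activity: str
    window_size: int
    fold: int
    iteration: int
    auc: float
    accuracy: float
    n_test_windows: int
    n_test_positives: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")
        if self.n_test_windows < 0 or self.n_test_positives < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class ActivityResult:
    """Per-activity aggregate mirroring one summary-table row."""

    activity: str
    activity_type: str
    window_size: int
    accuracy: float
    auc: float
    num_pos: int
    pos_pct: float


@dataclass
class WindowDataset:
    """Featurized windows at one window size, ready for modelling."""

    window_size: int
    X: np.ndarray  # (n_windows, n_features)
    labels: np.ndarray  # activity per window (no background)
    subjects: np.ndarray  # subject id per window
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("X/labels/subjects length mismatch")


def make_subject_folds(
    subject_ids: Sequence[str], k: int, seed: int
) -> CVSplit:
    """Random equal-as-possible partition of subjects into k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(dict.fromkeys(subject_ids))
    if len(ids) < k:
        raise ValueError(f"need at least {k} subjects, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_of = {ids[j]: int(i % k) for i, j in enumerate(order)}
    return CVSplit(fold_of=fold_of, k=k)


class SkippedRun(Exception):
    """A run could not be scored (no positives on one side); logged, not fatal."""


def train_eval_binary(
    ds: WindowDataset,
    activity: str,
    split: CVSplit,
    fold: int,
    iteration: int,
    seed: int,
    model_factory: ModelFactory = default_model_factory,
) -> RunResult:
    """Train one binary one-vs-rest model and evaluate it on the held-out fold.

    25% of training subjects are set aside as an inner validation split
    (re-drawn each iteration); the model never sees them, and test
    subjects are disjoint from all training subjects by construction.
    """
    train_subj, test_subj = split.train_test_subjects(fold)
    rng = np.random.default_rng([seed, fold, iteration])
    train_list = sorted(train_subj)
    n_val = max(1, int(round(VALIDATION_FRACTION * len(train_list)))) if len(train_list) > 1 else 0
    val_subj = set(rng.permutation(train_list)[:n_val])
    fit_subj = train_subj - val_subj

    in_fit = np.isin(ds.subjects, sorted(fit_subj))
    in_test = np.isin(ds.subjects, sorted(test_subj))
    y = (ds.labels == activity).astype(int)

    if y[in_fit].sum() == 0:
        raise SkippedRun(
            f"no training positives for {activity!r} in fold {fold}, iteration {iteration}"
        )
    if y[in_test].sum() == 0 or y[in_test].sum() == in_test.sum():
        raise SkippedRun(
            f"test fold {fold} lacks both classes for {activity!r}"
        )

    model_seed = int(rng.integers(0, 2**31 - 1))
    model = model_factory(model_seed)
    model.fit(ds.X[in_fit], y[in_fit])
    proba = model.predict_proba(ds.X[in_test])[:, 1]
    y_test = y[in_test]
    auc = float(roc_auc_score(y_test, proba))
    acc = float(accuracy_score(y_test, (proba >= 0.5).astype(int)))
    if auc < 0.5:
        logger.info(
            "run AUC %.3f below 0.5 for %s (fold %d, iteration %d)",
            auc, activity, fold, iteration,
        )
    return RunResult(
        activity=activity,
        window_size=ds.window_size,
        fold=fold,
        iteration=iteration,
        auc=auc,
        accuracy=acc,
        n_test_windows=int(in_test.sum()),
        n_test_positives=int(y_test.sum()),
    )


def weighted_auc(runs: Sequence[RunResult]) -> float:
    """Average run AUC weighted by each run's test-fold positive count."""
    if not runs:
        raise ValueError("need at least one run")
    w = np.array([r.n_test_positives for r in runs], dtype=float)
    if w.sum() == 0:
        raise ValueError("all run weights are zero")
    a = np.array([r.auc for r in runs])
    return float((a * w).sum() / w.sum())


def run_experiment(
    datasets: Mapping[int, WindowDataset],
    activities: Mapping[str, str] | Sequence[str],
    k: int = DEFAULT_FOLDS,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    bout_counts: Mapping[str, int] | None = None,
    model_factory: ModelFactory = default_model_factory,
    redraw_folds_per_window_size: bool = False,
) -> tuple[list[ActivityResult], list[RunResult]]:
    """Full experimental grid: k folds x iterations per activity per window size.

    ``activities`` maps activity name -> type (or is a plain sequence of
    names, typed "everyday").  Outer subject folds are fixed across
    window sizes unless ``redraw_folds_per_window_size`` is set.
    Returns per-activity aggregates (sorted by AUC descending within
    each window size) plus every individual run.
    """
    if isinstance(activities, Mapping):
        act_types = dict(activities)
    else:
        act_types = {a: "everyday" for a in activities}
    if not datasets:
        raise ValueError("no featurized window sizes supplied")

    all_subjects = sorted(
        {s for ds in datasets.values() for s in np.unique(ds.subjects)}
    )
    base_split = make_subject_folds(all_subjects, k, seed)

    if bout_counts is None:
        bout_counts = {}
    total_bouts = sum(bout_counts.values())

    run_results: list[RunResult] = []
    activity_results: list[ActivityResult] = []
    for ws in sorted(datasets):
        ds = datasets[ws]
        split = (
            make_subject_folds(all_subjects, k, seed + ws)
            if redraw_folds_per_window_size
            else base_split
        )
        per_activity: list[tuple[ActivityResult, list[RunResult]]] = []
        for activity, a_type in act_types.items():
            runs: list[RunResult] = []
            for fold in range(k):
                for it in range(iterations):
                    try:
                        runs.append(
                            train_eval_binary(
                                ds, activity, split, fold, it, seed,
                                model_factory=model_factory,
                            )
                        )
                    except SkippedRun as exc:
                        logger.warning("skipped run: %s", exc)
            if not runs:
                logger.warning(
                    "no scorable runs for %r at window size %d", activity, ws
                )
                continue
            num_pos = int(bout_counts.get(activity, 0))
            res = ActivityResult(
                activity=activity,
                activity_type=a_type,
                window_size=ws,
                accuracy=float(np.mean([r.accuracy for r in runs])),
                auc=weighted_auc(runs),
                num_pos=num_pos,
                pos_pct=100.0 * num_pos / total_bouts if total_bouts else float("nan"),
            )
            per_activity.append((res, runs))
            run_results.extend(runs)
        per_activity.sort(key=lambda pair: pair[0].auc, reverse=True)
        activity_results.extend(res for res, _ in per_activity)
    return activity_results, run_results


def make_window_folds(n_windows: int, k: int, seed: int) -> np.ndarray:
    """Window-level (subject-dependent) fold assignment."""
    rng = np.random.default_rng(seed)
    return rng.permutation(n_windows) % k


def _run_window_level(
    ds: WindowDataset,
    activity: str,
    k: int,
    iterations: int,
    seed: int,
    model_factory: ModelFactory,
) -> list[RunResult]:
    """Subject-dependent counterpart of the main loop: folds cut across windows."""
    y = (ds.labels == activity).astype(int)
    runs: list[RunResult] = []
    folds = make_window_folds(len(y), k, seed)
    for fold in range(k):
        in_test = folds == fold
        in_fit = ~in_test
        if y[in_fit].sum() == 0 or y[in_test].sum() in (0, in_test.sum()):
            logger.warning("skipped window-level run for %r fold %d", activity, fold)
            continue
        for it in range(iterations):
            rng = np.random.default_rng([seed, fold, it, 1])
            model = model_factory(int(rng.integers(0, 2**31 - 1)))
            model.fit(ds.X[in_fit], y[in_fit])
            proba = model.predict_proba(ds.X[in_test])[:, 1]
            runs.append(
                RunResult(
                    activity=activity,
                    window_size=ds.window_size,
                    fold=fold,
                    iteration=it,
                    auc=float(roc_auc_score(y[in_test], proba)),
                    accuracy=float(
                        accuracy_score(y[in_test], (proba >= 0.5).astype(int))
                    ),
                    n_test_windows=int(in_test.sum()),
                    n_test_positives=int(y[in_test].sum()),
                )
            )
    return runs


def subject_leakage_contrast(
    datasets: Mapping[int, WindowDataset],
    activity: str,
    k: int = DEFAULT_FOLDS,
    iterations: int = 1,
    seed: int = 0,
    model_factory: ModelFactory = default_model_factory,
) -> dict[int, tuple[float, float]]:
    """Paired AUCs per window size: (subject-dependent, subject-independent).

    The subject-dependent arm assigns overlapping windows to folds at
    random, so near-duplicate windows land on both sides of the split —
    the leakage mechanism the subject-level folds are designed to
    prevent.
    """
    out: dict[int, tuple[float, float]] = {}
    for ws in sorted(datasets):
        ds = datasets[ws]
        subjects = sorted(np.unique(ds.subjects))
        split = make_subject_folds(subjects, k, seed)
        indep_runs: list[RunResult] = []
        for fold in range(k):
            for it in range(iterations):
                try:
                    indep_runs.append(
                        train_eval_binary(
                            ds, activity, split, fold, it, seed,
                            model_factory=model_factory,
                        )
                    )
                except SkippedRun as exc:
                    logger.warning("skipped run: %s", exc)
        dep_runs = _run_window_level(ds, activity, k, iterations, seed, model_factory)
        if not indep_runs or not dep_runs:
            raise ValueError(
                f"activity {activity!r} not scorable at window size {ws}"
            )
        out[ws] = (weighted_auc(dep_runs), weighted_auc(indep_runs))
    return out
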