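"""First-stage multiclass machinery: Z-scoring, OAO/OAA linear SVMs, metrics.

Standardization statistics are always derived from training rows only and
applied unchanged downstream (leak-free): during cross-validation each fold
fits its own statistics, and the final refit uses global training statistics.
The one-against-one (OAO) decomposition trains N(N-1)/2 pairwise linear SVMs
(276 at N=24); prediction is majority vote with ties resolved to the lowest
class index.  Each pairwise model carries a Platt-style sigmoid calibrator so
its output can be read as the probability that the pair's lower-index class
wins — these calibrated scores are the second-level stacked features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .blocks import BlockMatrix, slice_by_chromosome


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

EPS_SD = 1e-8


@dataclass
class StandardizationStats:
    mean: np.ndarray
    sd: np.ndarray  # floored at EPS_SD for constant columns

    def checksum(self) -> float:
        return float(np.sum(self.mean) + np.sum(self.sd))


def fit_standardizer(train_matrix: np.ndarray) -> StandardizationStats:
    X = np.asarray(train_matrix, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    sd = np.where(sd < EPS_SD, EPS_SD, sd)
    return StandardizationStats(mean=mean, sd=sd)


def apply_standardizer(stats: StandardizationStats, matrix: np.ndarray) -> np.ndarray:
    return (np.asarray(matrix, dtype=np.float64) - stats.mean) / stats.sd


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _prf(y_true, y_pred, classes):
    return precision_recall_fscore_support(
        y_true, y_pred, labels=list(classes), zero_division=0
    )


def macro_f1(y_true, y_pred, classes) -> float:
    """Unweighted mean of per-class F1 over the fixed class list."""
    _, _, f1, _ = _prf(y_true, y_pred, classes)
    return float(np.mean(f1))


def weighted_f1(y_true, y_pred, classes) -> float:
    p, r, f1, support = _prf(y_true, y_pred, classes)
    total = support.sum()
    if total == 0:
        return 0.0
    return float(np.sum(f1 * support) / total)


def macro_precision(y_true, y_pred, classes) -> float:
    p, _, _, _ = _prf(y_true, y_pred, classes)
    return float(np.mean(p))


def macro_recall(y_true, y_pred, classes) -> float:
    _, r, _, _ = _prf(y_true, y_pred, classes)
    return float(np.mean(r))


# ---------------------------------------------------------------------------
# OAO / OAA model sets
# ---------------------------------------------------------------------------


@dataclass
class CVPlan:
    folds: int = 5
    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    seed: int = 0


@dataclass
class _PairModel:
    svm: LinearSVC
    calibrator: LogisticRegression  # 1-D logistic on the decision value


@dataclass
class OAOModelSet:
    classes: tuple[int, ...]
    pair_models: dict[tuple[int, int], _PairModel]
    C: float
    stats: StandardizationStats
    cv_fold_stats: list[StandardizationStats] = field(default_factory=list)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Lexicographic (i, j), i < j — the serialized score order."""
        cls = self.classes
        return [(cls[a], cls[b]) for a in range(len(cls)) for b in range(a + 1, len(cls))]


@dataclass
class OAAModelSet:
    classes: tuple[int, ...]
    per_class_models: dict[int, LinearSVC]
    C: float
    stats: StandardizationStats


def _fit_svm(X, y, C) -> LinearSVC:
    svm = LinearSVC(C=C)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svm.fit(X, y)
    return svm


def _fit_pairwise(X, y, classes, C, calibrate=True):
    models = {}
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            i, j = classes[a], classes[b]
            sel = (y == i) | (y == j)
            Xp = X[sel]
            # target 1 = lower-index class wins
            t = (y[sel] == i).astype(int)
            svm = _fit_svm(Xp, t, C)
            calib = None
            if calibrate:
                d = svm.decision_function(Xp).reshape(-1, 1)
                # Platt scaling is conventionally unregularized: large C
                calib = LogisticRegression(C=1e6, max_iter=1000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    calib.fit(d, t)
            models[(i, j)] = _PairModel(svm=svm, calibrator=calib)
    return models


def _oao_votes(models: dict, classes, X) -> np.ndarray:
    """Vote matrix (n_samples, n_classes); zero decision favors the lower index."""
    index = {c: k for k, c in enumerate(classes)}
    votes = np.zeros((X.shape[0], len(classes)), dtype=np.int64)
    for (i, j), pm in models.items():
        d = pm.svm.decision_function(X)
        votes[:, index[i]] += (d >= 0).astype(np.int64)
        votes[:, index[j]] += (d < 0).astype(np.int64)
    return votes


def predict_oao(model_set: OAOModelSet, X) -> np.ndarray:
    """Majority vote over pairwise decisions; ties go to the lowest class."""
    X = np.asarray(X, dtype=np.float64)
    votes = _oao_votes(model_set.pair_models, model_set.classes, X)
    # argmax returns the first (lowest-index) maximum; classes are ascending
    return np.asarray(model_set.classes)[votes.argmax(axis=1)]


def oao_scores(model_set: OAOModelSet, X) -> np.ndarray:
    """Calibrated pairwise scores in [0, 1], lexicographic pair order.

    Entry (i, j) is the calibrated probability that class i (the pair's
    lower index) wins the pairwise contest.
    """
    X = np.asarray(X, dtype=np.float64)
    cols = []
    for pair in model_set.pairs:
        pm = model_set.pair_models[pair]
        if pm.calibrator is None:
            raise ValueError("model set was trained without calibration")
        d = pm.svm.decision_function(X).reshape(-1, 1)
        cols.append(pm.calibrator.predict_proba(d)[:, 1])
    return np.clip(np.column_stack(cols), 0.0, 1.0)


def _usable_classes(y, min_count=2):
    values, counts = np.unique(y, return_counts=True)
    usable = tuple(int(v) for v, c in zip(values, counts) if c >= min_count)
    dropped = [int(v) for v, c in zip(values, counts) if c < min_count]
    if dropped:
        warnings.warn(f"classes with < {min_count} samples excluded: {dropped}")
    return usable


def _cv_select_C(X, y, classes, plan: CVPlan, fit_predict):
    """Pick C by mean cross-validated macro-F1; per-fold standardization.

    Returns (best_C, per-fold standardization stats of the winning C).
    """
    min_count = int(np.min(np.unique(y, return_counts=True)[1]))
    n_splits = max(2, min(plan.folds, min_count))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=plan.seed)
    folds = list(skf.split(X, y))
    results = {}
    fold_stats_by_C = {}
    for C in plan.C_grid:
        scores = []
        fold_stats = []
        for tr, va in folds:
            stats = fit_standardizer(X[tr])
            fold_stats.append(stats)
            Xtr = apply_standardizer(stats, X[tr])
            Xva = apply_standardizer(stats, X[va])
            y_hat = fit_predict(Xtr, y[tr], Xva, C)
            scores.append(macro_f1(y[va], y_hat, classes))
        results[C] = float(np.mean(scores))
        fold_stats_by_C[C] = fold_stats
    best_C = max(plan.C_grid, key=lambda c: (results[c], -c))  # ties -> smaller C
    return best_C, fold_stats_by_C[best_C], results


def train_oao(
    X, y, plan: CVPlan | None = None, C: float | None = None, calibrate: bool = True
) -> OAOModelSet:
    """Train the one-against-one set; C by 5-fold CV unless fixed explicitly.

    ``X`` is the raw (unstandardized) training matrix; the returned model set
    owns its global standardization statistics and expects raw inputs at
    prediction time to pass through :func:`oao_input`.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    plan = plan or CVPlan()
    classes = _usable_classes(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 usable classes")
    keep = np.isin(y, classes)
    X, y = X[keep], y[keep]

    cv_fold_stats: list[StandardizationStats] = []
    if C is None:

        def fit_predict(Xtr, ytr, Xva, c):
            models = _fit_pairwise(Xtr, ytr, classes, c, calibrate=False)
            votes = _oao_votes(models, classes, Xva)
            return np.asarray(classes)[votes.argmax(axis=1)]

        C, cv_fold_stats, _ = _cv_select_C(X, y, classes, plan, fit_predict)

    stats = fit_standardizer(X)
    Xs = apply_standardizer(stats, X)
    models = _fit_pairwise(Xs, y, classes, C, calibrate=calibrate)
    return OAOModelSet(
        classes=classes, pair_models=models, C=float(C), stats=stats,
        cv_fold_stats=cv_fold_stats,
    )


def oao_input(model_set: OAOModelSet, X) -> np.ndarray:
    """Standardize raw features with the model set's training statistics."""
    return apply_standardizer(model_set.stats, X)


def train_oaa(X, y, plan: CVPlan | None = None, C: float | None = None) -> OAAModelSet:
    """One-against-all counterpart: N binary models, argmax decision."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    plan = plan or CVPlan()
    classes = _usable_classes(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 usable classes")
    keep = np.isin(y, classes)
    X, y = X[keep], y[keep]

    if C is None:

        def fit_predict(Xtr, ytr, Xva, c):
            models = {
                k: _fit_svm(Xtr, (ytr == k).astype(int), c) for k in classes
            }
            scores = np.column_stack(
                [models[k].decision_function(Xva) for k in classes]
            )
            return np.asarray(classes)[scores.argmax(axis=1)]

        C, _, _ = _cv_select_C(X, y, classes, plan, fit_predict)

    stats = fit_standardizer(X)
    Xs = apply_standardizer(stats, X)
    models = {k: _fit_svm(Xs, (y == k).astype(int), C) for k in classes}
    return OAAModelSet(classes=classes, per_class_models=models, C=float(C), stats=stats)


def predict_oaa(model_set: OAAModelSet, X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    scores = np.column_stack(
        [model_set.per_class_models[k].decision_function(X) for k in model_set.classes]
    )
    return np.asarray(model_set.classes)[scores.argmax(axis=1)]


# ---------------------------------------------------------------------------
# GA fitness
# ---------------------------------------------------------------------------


def make_ga_fitness(
    train_matrix: BlockMatrix,
    eval_matrix: BlockMatrix,
    y_train,
    y_eval,
    C: float = 1.0,
):
    """Fitness = held-out macro-F1 of an OAO model on the selected blocks.

    A single fixed C keeps the 400-evaluation GA tractable; the final
    reported models re-tune C on the full grid.
    """
    y_train = np.asarray(y_train)
    y_eval = np.asarray(y_eval)
    classes = tuple(int(v) for v in np.unique(y_train))

    def fitness(chromosome) -> float:
        Xtr = slice_by_chromosome(train_matrix, chromosome).values
        Xev = slice_by_chromosome(eval_matrix, chromosome).values
        model = train_oao(Xtr, y_train, C=C, calibrate=False)
        y_hat = predict_oao(model, oao_input(model, Xev))
        return macro_f1(y_eval, y_hat, classes)

    return fitness
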