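"""Multi-label stage: iterative stratification, Binary Relevance, Label Powerset.

The split preserves per-label proportions greedily, rarest label first
(iterative stratification); samples pinned to the training side (the phase-1
training set) are placed before stratifying the rest.  Binary Relevance (BR)
fits one independent binary classifier per label; Label Powerset (LP) maps
each observed label combination to a single multiclass target, so it can
never emit a combination unseen in training.  Four base learner families are
supported: linear SVM (C tuned on {0.01, 0.1, 1, 10} by cross-validation),
logistic regression, decision tree and k-nearest neighbors (k in {1, 3}),
the latter three at library defaults.  Evaluation reports per-class
precision/recall/F1 plus macro (unweighted over the full class list, absent
classes scoring 0) and support-weighted aggregates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .io import SplitSpec

C_GRID = (0.01, 0.1, 1.0, 10.0)


# ---------------------------------------------------------------------------
# iterative stratification
# ---------------------------------------------------------------------------


def iterative_stratified_split(
    ids,
    label_sets,
    ratio: float = 0.8,
    pinned_train_ids=(),
    seed: int = 0,
) -> SplitSpec:
    """Greedy multi-label stratified split.

    Labels are processed in increasing frequency order; each remaining sample
    carrying the current label goes to the side with the greatest remaining
    demand for that label, ties broken by larger remaining global budget,
    then by a seeded coin flip.  ``pinned_train_ids`` are forced into the
    training side before stratification.
    """
    ids = list(ids)
    label_sets = [frozenset(s) for s in label_sets]
    if len(ids) != len(label_sets):
        raise ValueError("ids and label_sets length mismatch")
    by_id = dict(zip(ids, label_sets))
    pinned = [i for i in ids if i in set(pinned_train_ids)]
    missing = set(pinned_train_ids) - set(ids)
    if missing:
        raise ValueError(f"pinned ids not in records: {sorted(missing)[:5]}")
    n = len(ids)
    budget = {"train": ratio * n, "test": (1 - ratio) * n}
    if len(pinned) > budget["train"] + 1e-9:
        raise ValueError("pinned ids exceed the training budget")

    label_counts: Counter = Counter()
    for s in label_sets:
        label_counts.update(s)
    # per-side desired counts per label
    demand = {
        side: {l: frac * c for l, c in label_counts.items()}
        for side, frac in (("train", ratio), ("test", 1 - ratio))
    }

    rng = np.random.default_rng(seed)
    assigned: dict[str, str] = {}
    for i in pinned:
        assigned[i] = "train"
        budget["train"] -= 1
        for l in by_id[i]:
            demand["train"][l] -= 1

    remaining = set(ids) - set(pinned)
    # rarest label first; deterministic tie-break by label value
    for label in sorted(label_counts, key=lambda l: (label_counts[l], l)):
        carrying = sorted(i for i in remaining if label in by_id[i])
        for i in carrying:
            d_tr, d_te = demand["train"][label], demand["test"][label]
            if d_tr > d_te:
                side = "train"
            elif d_te > d_tr:
                side = "test"
            elif budget["train"] > budget["test"]:
                side = "train"
            elif budget["test"] > budget["train"]:
                side = "test"
            else:
                side = "train" if rng.uniform() < 0.5 else "test"
            assigned[i] = side
            remaining.discard(i)
            budget[side] -= 1
            for l in by_id[i]:
                demand[side][l] -= 1
    # samples with no labels (not expected) fall back to budget balance
    for i in sorted(remaining):
        side = "train" if budget["train"] >= budget["test"] else "test"
        assigned[i] = side
        budget[side] -= 1

    train = tuple(i for i in ids if assigned[i] == "train")
    test = tuple(i for i in ids if assigned[i] == "test")
    return SplitSpec(
        train_ids=train,
        test_ids=test,
        ratio=ratio,
        strategy="iterative_stratification",
    )


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaseLearner:
    """Base classifier family: linear_svm | logistic | decision_tree | knn."""

    kind: str
    k: int = 1
    C: float | None = None  # None -> cross-validated on C_GRID
    seed: int = 0

    def make(self, C: float | None = None):
        if self.kind == "linear_svm":
            return LinearSVC(C=C if C is not None else (self.C or 1.0))
        if self.kind == "logistic":
            return LogisticRegression(max_iter=1000)
        if self.kind == "decision_tree":
            return DecisionTreeClassifier(random_state=self.seed)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.k)
        raise ValueError(f"unknown base learner: {self.kind!r}")


def _fit_quiet(clf, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def _confidence(clf, X) -> np.ndarray:
    """Positive-class confidence on a comparable scale per classifier."""
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=np.float64)
    proba = clf.predict_proba(X)
    pos = list(clf.classes_).index(1) if 1 in clf.classes_ else None
    if pos is None:
        return np.full(X.shape[0], -np.inf)
    return proba[:, pos] - 0.5


def _cv_macro_f1_multiclass(X, y, make_clf, C_grid, folds=5, seed=0):
    """Select C for a multiclass learner by mean CV macro-F1 over combos."""
    from .stage1 import macro_f1

    counts = np.unique(y, return_counts=True)[1]
    n_splits = max(2, min(folds, int(counts.min())))
    if n_splits < 2 or len(counts) < 2:
        return C_grid[len(C_grid) // 2]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    classes = list(np.unique(y))
    best, best_score = None, -1.0
    for C in C_grid:
        scores = []
        for tr, va in skf.split(X, y):
            if len(np.unique(y[tr])) < 2:
                continue
            clf = _fit_quiet(make_clf(C), X[tr], y[tr])
            scores.append(macro_f1(y[va], clf.predict(X[va]), classes))
        mean = float(np.mean(scores)) if scores else -1.0
        if mean > best_score:
            best, best_score = C, mean
    return best


# ---------------------------------------------------------------------------
# Binary Relevance
# ---------------------------------------------------------------------------


@dataclass
class MultiLabelModel:
    strategy: str  # BR | LP
    base: BaseLearner
    n_classes: int
    label_models: dict = field(default_factory=dict)  # BR: label -> clf or None
    lp_model: object = None
    codebook: "LabelPowersetCodebook | None" = None
    C: float | None = None


def _label_matrix(label_sets, n_classes) -> np.ndarray:
    Y = np.zeros((len(label_sets), n_classes), dtype=int)
    for r, s in enumerate(label_sets):
        for l in s:
            Y[r, l] = 1
    return Y


def fit_br(X, label_sets, base: BaseLearner, n_classes: int = 28) -> MultiLabelModel:
    """One independent binary classifier per label.

    Labels with no positive training samples get an always-negative stub
    (``None``), with a warning.  For the linear-SVM base a single shared C is
    selected by cross-validated macro-F1 over the per-label binary tasks.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = _label_matrix(label_sets, n_classes)
    C = base.C
    if base.kind == "linear_svm" and C is None:
        C = _select_br_svm_C(X, Y, base)
    models: dict[int, object] = {}
    for l in range(n_classes):
        y = Y[:, l]
        if y.sum() == 0:
            warnings.warn(f"label {l} has no positive training samples; stubbed")
            models[l] = None
        elif y.sum() == len(y):
            models[l] = "always_positive"
        else:
            models[l] = _fit_quiet(base.make(C), X, y)
    return MultiLabelModel(
        strategy="BR", base=base, n_classes=n_classes, label_models=models, C=C
    )


def _select_br_svm_C(X, Y, base: BaseLearner, folds: int = 5):
    from .stage1 import macro_f1

    active = [l for l in range(Y.shape[1]) if 0 < Y[:, l].sum() < Y.shape[0]]
    if not active:
        return 1.0
    best, best_score = None, -1.0
    for C in C_GRID:
        scores = []
        for l in active:
            y = Y[:, l]
            counts = np.unique(y, return_counts=True)[1]
            n_splits = max(2, min(folds, int(counts.min())))
            if int(counts.min()) < 2:
                continue
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=base.seed)
            for tr, va in skf.split(X, y):
                if len(np.unique(y[tr])) < 2:
                    continue
                clf = _fit_quiet(base.make(C), X[tr], y[tr])
                scores.append(macro_f1(y[va], clf.predict(X[va]), [0, 1]))
        mean = float(np.mean(scores)) if scores else -1.0
        if mean > best_score:
            best, best_score = C, mean
    return best if best is not None else 1.0


def predict_br(model: MultiLabelModel, X) -> list[frozenset[int]]:
    """Labels whose classifier fires; empty sets fall back to the single most
    confident label (an empty prediction would unfairly zero recall)."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    fired = np.zeros((n, model.n_classes), dtype=bool)
    conf = np.full((n, model.n_classes), -np.inf)
    for l, clf in model.label_models.items():
        if clf is None:
            continue
        if clf == "always_positive":
            fired[:, l] = True
            conf[:, l] = 0.0
            continue
        fired[:, l] = clf.predict(X) == 1
        conf[:, l] = _confidence(clf, X)
    out = []
    for r in range(n):
        labels = frozenset(np.flatnonzero(fired[r]))
        if not labels:
            labels = frozenset([int(conf[r].argmax())])
        out.append(labels)
    return out


# ---------------------------------------------------------------------------
# Label Powerset
# ---------------------------------------------------------------------------


@dataclass
class LabelPowersetCodebook:
    """Bijection between training-observed label sets and integer codes."""

    combo_to_code: dict[frozenset, int]
    code_to_combo: dict[int, frozenset]

    @classmethod
    def from_label_sets(cls, label_sets) -> "LabelPowersetCodebook":
        combos = sorted({frozenset(s) for s in label_sets}, key=lambda s: sorted(s))
        c2i = {c: k for k, c in enumerate(combos)}
        return cls(combo_to_code=c2i, code_to_combo={k: c for c, k in c2i.items()})

    def encode(self, label_set) -> int:
        return self.combo_to_code[frozenset(label_set)]

    def decode(self, code: int) -> frozenset:
        return self.code_to_combo[int(code)]

    def __len__(self) -> int:
        return len(self.combo_to_code)


def fit_lp(X, label_sets, base: BaseLearner, n_classes: int = 28) -> MultiLabelModel:
    """Single multiclass model over label-combination codes."""
    X = np.asarray(X, dtype=np.float64)
    codebook = LabelPowersetCodebook.from_label_sets(label_sets)
    y = np.array([codebook.encode(s) for s in label_sets])
    C = base.C
    if base.kind == "linear_svm" and C is None:
        C = _cv_macro_f1_multiclass(X, y, base.make, C_GRID, seed=base.seed)
    if len(codebook) == 1:
        clf = None  # degenerate: single observed combo, constant prediction
    else:
        clf = _fit_quiet(base.make(C), X, y)
    return MultiLabelModel(
        strategy="LP", base=base, n_classes=n_classes,
        lp_model=clf, codebook=codebook, C=C,
    )


def predict_lp(model: MultiLabelModel, X) -> list[frozenset[int]]:
    X = np.asarray(X, dtype=np.float64)
    if model.lp_model is None:
        combo = model.codebook.decode(0)
        return [combo] * X.shape[0]
    codes = model.lp_model.predict(X)
    return [model.codebook.decode(c) for c in codes]


def fit_predict_multilabel(strategy, X_train, sets_train, X_test, base, n_classes=28):
    if strategy == "BR":
        model = fit_br(X_train, sets_train, base, n_classes)
        return model, predict_br(model, X_test)
    if strategy == "LP":
        model = fit_lp(X_train, sets_train, base, n_classes)
        return model, predict_lp(model, X_test)
    raise ValueError(f"unknown strategy: {strategy!r}")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    macro_f1: float
    weighted_f1: float
    macro_precision: float
    macro_recall: float
    per_class: pd.DataFrame
    subset_accuracy: float

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "subset_accuracy": self.subset_accuracy,
        }


def evaluate(predictions, truth, n_classes: int = 28) -> MetricsReport:
    """Label-wise precision/recall/F1 with macro and support-weighted means.

    Macro averages run over the full ``n_classes`` label list; a class absent
    from both truth and predictions contributes 0 to the macro mean.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth length mismatch")
    P = _label_matrix(predictions, n_classes)
    T = _label_matrix(truth, n_classes)
    rows = []
    for l in range(n_classes):
        tp = int(np.sum(P[:, l] & T[:, l]))
        fp = int(np.sum(P[:, l] & ~T[:, l].astype(bool)))
        fn = int(np.sum(~P[:, l].astype(bool) & T[:, l]))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append(
            {"label": l, "precision": prec, "recall": rec, "f1": f1,
             "support": int(T[:, l].sum())}
        )
    table = pd.DataFrame(rows).set_index("label")
    support = table["support"].to_numpy()
    total = support.sum()
    weighted = float((table["f1"].to_numpy() * support).sum() / total) if total else 0.0
    subset = float(np.mean([frozenset(p) == frozenset(t) for p, t in zip(predictions, truth)]))
    return MetricsReport(
        macro_f1=float(table["f1"].mean()),
        weighted_f1=weighted,
        macro_precision=float(table["precision"].mean()),
        macro_recall=float(table["recall"].mean()),
        per_class=table,
        subset_accuracy=subset,
    )
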