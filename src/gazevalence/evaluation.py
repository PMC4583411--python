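"""Classification protocol: repeated class-balanced cross-validation,
one-vs-rest SVMs, and Bookmaker informedness scoring.

The generalization protocol is 10 repetitions of a 10-fold scheme with
train/validation/test proportions 0.9/0.05/0.05.  Validation and test
sets are drawn with an equal number of images per valence class; the
validation set selects SVM hyperparameters, the test set is scored.
Performance is summarized by the confusion matrix, classification
accuracy, and Bookmaker informedness — a chance-corrected score in
[-1, 1] with 0 at chance — which is prevalence-weighted per-class
Youden's J in the multiclass one-vs-rest decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .gaze_data import CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan", "FoldResult", "FoldAssignment", "make_cv_plan", "train_eval",
    "bookmaker", "accuracy", "confusion_matrix3", "aggregate",
    "DEFAULT_GRIDS",
]

# Small hyperparameter grids searched on the validation split.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "linear": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "rbf": [{"C": c, "gamma": "scale"} for c in (0.1, 1.0, 10.0)],
    "poly": [
        {"C": c, "degree": d, "gamma": "scale"}
        for c in (0.1, 1.0, 10.0) for d in (2, 3)
    ],
}


@dataclass(frozen=True)
class FoldAssignment:
    repeat: int
    fold: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


@dataclass
class CVPlan:
    """Index assignments for every repeat x fold of the protocol."""

    n_repeats: int
    n_folds: int
    ratios: tuple[float, float, float]
    seed: int
    classes: tuple[str, ...]
    assignments: list[FoldAssignment] = field(repr=False, default_factory=list)

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self):
        return len(self.assignments)


def make_cv_plan(
    labels,
    n_repeats: int = 10,
    n_folds: int = 10,
    ratios: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
    classes: tuple[str, ...] = CLASSES,
) -> CVPlan:
    """Build the repeated class-balanced train/validation/test plan.

    For every repeat x fold, the validation and test sets each hold
    ``max(1, round(ratio * min class count))`` images per class, drawn
    without replacement; all remaining images train.  Deterministic for a
    given ``seed``.
    """
    labels = np.asarray(labels)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    present = [c for c in classes if np.any(labels == c)]
    if len(present) < len(classes):
        missing = sorted(set(classes) - set(present))
        raise ValueError(f"no items in class(es) {missing}")
    per_class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    min_count = min(len(v) for v in per_class_idx.values())
    if min_count < n_folds:
        raise ValueError(
            f"smallest class has {min_count} items; needs at least {n_folds}"
        )
    n_val = max(1, round(ratios[1] * min_count))
    n_test = max(1, round(ratios[2] * min_count))
    if n_val + n_test > min_count:
        raise ValueError("validation+test draw exceeds the smallest class")

    rng = np.random.default_rng(seed)
    universe = np.arange(len(labels))
    assignments = []
    for rep in range(n_repeats):
        for fold in range(n_folds):
            val, test = [], []
            for c in classes:
                draw = rng.choice(per_class_idx[c], size=n_val + n_test, replace=False)
                val.extend(draw[:n_val])
                test.extend(draw[n_val:])
            val = np.sort(np.array(val))
            test = np.sort(np.array(test))
            train = np.setdiff1d(universe, np.concatenate([val, test]))
            assignments.append(
                FoldAssignment(repeat=rep, fold=fold, train=train,
                               validation=val, test=test)
            )
    return CVPlan(
        n_repeats=n_repeats, n_folds=n_folds, ratios=tuple(ratios),
        seed=seed, classes=tuple(classes), assignments=assignments,
    )


# ---------------------------------------------------------------------------
# scoring

def confusion_matrix3(y_true, y_pred, classes: tuple[str, ...] = CLASSES) -> np.ndarray:
    """Confusion counts; rows are true classes, columns predictions, both
    in canonical (unpleasant, neutral, pleasant) order."""
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def bookmaker(confusion: np.ndarray, weighted: bool = True) -> float:
    """Multiclass Bookmaker informedness of a confusion matrix.

    Per class c (one-vs-rest): recall = TP / (TP + FN) and inverse recall
    = TN / (TN + FP); the class informedness is their sum minus 1
    (Youden's J).  Classes are averaged weighted by prevalence (row sum /
    total) by default, or uniformly over non-empty classes with
    ``weighted=False``.  +1 is perfectly informed, 0 chance level, -1
    perversely incorrect.  A class with no true items contributes 0 with
    zero weight.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total == 0:
        raise ValueError("informedness undefined for an empty confusion matrix")
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    tp = np.diag(cm)
    j = np.zeros(len(row))
    nonempty = row > 0
    recall = np.where(nonempty, tp / np.where(nonempty, row, 1), 0.0)
    fp = col - tp
    tn = total - row - fp
    denom = tn + fp  # = total - row; 0 only if one class holds everything
    inv_recall = np.where(denom > 0, tn / np.where(denom > 0, denom, 1), 1.0)
    j = np.where(nonempty, recall + inv_recall - 1.0, 0.0)
    if weighted:
        return float(j @ (row / total))
    return float(j[nonempty].mean())


def accuracy(confusion: np.ndarray) -> float:
    """Fraction of correct predictions: trace over total."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm) / total)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FoldResult:
    repeat: int
    fold: int
    kernel: str
    confusion: np.ndarray
    bookmaker: float
    accuracy: float
    params: dict


def _fit_ovr_svm(X_train, y_train, kernel: str, params: dict) -> OneVsRestClassifier:
    clf = OneVsRestClassifier(SVC(kernel=kernel, **params))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_train, y_train)
    return clf


def train_eval(
    features,
    labels,
    plan: CVPlan,
    kernel: str = "linear",
    grid: list[dict] | None = None,
    classes: tuple[str, ...] = CLASSES,
    transform_factory=None,
) -> list[FoldResult]:
    """Run the full repeated-CV protocol for one kernel.

    Per fold: features are standardized on the training rows; one-vs-rest
    SVMs are fitted for every hyperparameter setting in ``grid``; the
    setting with the best validation Bookmaker score (ties: first in the
    grid) is evaluated on the test rows.  Folds whose training set misses
    a class are skipped with a warning.

    ``transform_factory``, if given, returns a fresh fit/transform object
    (e.g. a variance reducer) that is fitted on the standardized training
    rows of each fold and applied to all three splits.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels are not row-aligned")
    if grid is None:
        grid = DEFAULT_GRIDS[kernel]
    results = []
    for fa in plan:
        if len(set(y[fa.train])) < len(classes):
            logger.warning(
                "skipping repeat %d fold %d: class missing from training set",
                fa.repeat, fa.fold,
            )
            continue
        scaler = StandardScaler().fit(X[fa.train])
        Xtr = scaler.transform(X[fa.train])
        Xva = scaler.transform(X[fa.validation])
        Xte = scaler.transform(X[fa.test])
        if transform_factory is not None:
            reducer = transform_factory()
            reducer.fit(Xtr)
            Xtr = reducer.transform(Xtr)
            Xva = reducer.transform(Xva)
            Xte = reducer.transform(Xte)
        best = None
        for params in grid:
            clf = _fit_ovr_svm(Xtr, y[fa.train], kernel, params)
            score = bookmaker(
                confusion_matrix3(y[fa.validation], clf.predict(Xva), classes)
            )
            if best is None or score > best[0]:
                best = (score, params, clf)
        _, params, clf = best
        cm = confusion_matrix3(y[fa.test], clf.predict(Xte), classes)
        results.append(
            FoldResult(
                repeat=fa.repeat, fold=fa.fold, kernel=kernel, confusion=cm,
                bookmaker=bookmaker(cm), accuracy=accuracy(cm), params=params,
            )
        )
    return results


def aggregate(results: list[FoldResult]) -> dict:
    """Means and standard errors across folds, plus the pooled confusion."""
    if not results:
        raise ValueError("no fold results to aggregate")
    bm = np.array([r.bookmaker for r in results])
    acc = np.array([r.accuracy for r in results])
    k = len(results)

    def se(v):
        return float(v.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0

    return {
        "n_folds": k,
        "mean_bookmaker": float(bm.mean()),
        "se_bookmaker": se(bm),
        "mean_accuracy": float(acc.mean()),
        "se_accuracy": se(acc),
        "pooled_confusion": np.sum([r.confusion for r in results], axis=0),
    }
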