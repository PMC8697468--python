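"""Repeated stratified k-fold evaluation and classification metrics.

The evaluation protocol is 4-fold stratified cross-validation repeated 20
times with different partitions, reporting mean accuracy, the variance of
the fold-level accuracies, micro/macro F1 and a pooled confusion matrix.
Stratification is per-class round-robin after a seeded shuffle, which
guarantees every test fold contains every class (fold sizes differ by at
most one per class).

``compare_reducers`` runs several dimension-reduction front-ends through
the identical fold plan (a paired comparison) ahead of a shared classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """C x C counts; rows = true class, columns = predicted class."""

    class_names: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.class_names)
        if self.counts.shape != (C, C):
            raise ValueError("confusion matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     class_names: Sequence[str]) -> ConfusionMatrix:
    C = len(class_names)
    counts = np.zeros((C, C), dtype=np.int64)
    np.add.at(counts, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
    return ConfusionMatrix(list(class_names), counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def micro_f1(cm: ConfusionMatrix) -> float:
    """F1 from globally pooled per-class TP/FP/FN.

    In single-label multiclass scoring every false positive is another
    class's false negative, so this equals accuracy.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts).sum()
    fp = cm.counts.sum(axis=0).sum() - tp
    fn = cm.counts.sum(axis=1).sum() - tp
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0

def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class one-vs-rest F1 scores.

    A class with no true and no predicted instances has undefined F1 and
    contributes 0, with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts).astype(float)
    fp = cm.counts.sum(axis=0) - tp
    fn = cm.counts.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    undefined = denom == 0
    if undefined.any():
        warnings.warn(
            f"classes {list(np.flatnonzero(undefined))} have undefined F1; counted as 0",
            stacklevel=2,
        )
    f1 = np.zeros_like(tp)
    np.divide(2 * tp, denom, out=f1, where=~undefined)
    return float(f1.mean())


# ---------------------------------------------------------------------------
# Fold construction


def stratified_kfold(labels: np.ndarray, k: int = 4, seed: int = 0) -> list[np.ndarray]:
    """One repeat of stratified k-fold: list of k disjoint test-index arrays.

    Within each class, indices are shuffled with the seed and dealt
    round-robin to folds, so per-class fold sizes differ by at most one and
    every test fold covers every class.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has only {idx.size} members, fewer than k={k} folds"
            )
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class FoldPlan:
    """k folds x repeats of test-index sets; repeat r is seeded seed + r."""

    k: int = 4
    repeats: int = 20
    seed: int = 0
    plans: list[list[np.ndarray]] = field(default_factory=list)

    @classmethod
    def build(cls, labels: np.ndarray, k: int = 4, repeats: int = 20,
              seed: int = 0) -> "FoldPlan":
        plans = [stratified_kfold(labels, k, seed + r) for r in range(repeats)]
        return cls(k=k, repeats=repeats, seed=seed, plans=plans)


@dataclass
class CvResult:
    per_fold_accuracy: np.ndarray  # (repeats, k)
    mean_accuracy: float
    variance: float  # over all k*repeats fold accuracies
    micro_f1: float
    macro_f1: float
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "variance": self.variance,
            "micro_f1": self.micro_f1,
            "macro_f1": self.macro_f1,
            "per_fold_accuracy": self.per_fold_accuracy.tolist(),
            "confusion": self.confusion.counts.tolist(),
            "class_names": self.confusion.class_names,
        }


def repeated_cv(ds, model_factory: Callable, k: int = 4, repeats: int = 20,
                seed: int = 0, plan: FoldPlan | None = None) -> CvResult:
    """Repeated stratified k-fold CV of ``model_factory()`` on a dataset.

    The model is refitted from scratch on every training split; fold
    accuracies are aggregated over all ``k * repeats`` folds and confusion
    counts pooled.  ``model_factory`` must return an object with ``fit`` and
    ``predict``; it may accept a ``seed`` keyword for per-fold reseeding.
    """
    X, y = ds.X, ds.y
    names = list(ds.class_names)
    if plan is None:
        plan = FoldPlan.build(y, k, repeats, seed)
    accs = np.empty((plan.repeats, plan.k))
    pooled = np.zeros((len(names), len(names)), dtype=np.int64)
    all_idx = np.arange(len(y))
    for r, folds in enumerate(plan.plans):
        for j, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            model = _make_model(model_factory, seed=plan.seed + r)
            model.fit(X[train_idx], y[train_idx])
            pred = np.asarray(model.predict(X[test_idx]))
            cm = confusion_matrix(y[test_idx], pred, names)
            pooled += cm.counts
            accs[r, j] = accuracy(cm)
    confusion = ConfusionMatrix(names, pooled)
    return CvResult(
        per_fold_accuracy=accs,
        mean_accuracy=float(accs.mean()),
        variance=float(accs.var()),
        micro_f1=micro_f1(confusion),
        macro_f1=macro_f1(confusion),
        confusion=confusion,
    )


def _make_model(factory: Callable, seed: int):
    try:
        return factory(seed=seed)
    except TypeError:
        return factory()


def compare_reducers(ds, reducers: Mapping[str, Callable],
                     classifier_factory: Callable, k: int = 4,
                     repeats: int = 20, seed: int = 0) -> dict:
    """Paired comparison of dimension-reduction front-ends.

    ``reducers`` maps a method name to a factory returning an object with
    ``fit(X, y)`` and ``transform(X)``.  Every method is evaluated on the
    identical fold plan ahead of a fresh ``classifier_factory()`` per fold.
    Returns a report dict with per-method mean accuracy / micro-F1 and
    per-fold detail.
    """
    if not reducers:
        raise ValueError("need at least one reduction method")
    X, y = ds.X, ds.y
    names = list(ds.class_names)
    plan = FoldPlan.build(y, k, repeats, seed)
    report: dict = {"k": k, "repeats": repeats, "seed": seed, "methods": {}}
    all_idx = np.arange(len(y))
    for method, reducer_factory in reducers.items():
        accs = []
        pooled = np.zeros((len(names), len(names)), dtype=np.int64)
        for r, folds in enumerate(plan.plans):
            for test_idx in folds:
                train_idx = np.setdiff1d(all_idx, test_idx)
                reducer = _make_model(reducer_factory, seed=plan.seed + r)
                reducer.fit(X[train_idx], y[train_idx])
                Ztr = reducer.transform(X[train_idx])
                Zte = reducer.transform(X[test_idx])
                clf = _make_model(classifier_factory, seed=plan.seed + r)
                clf.fit(Ztr, y[train_idx])
                cm = confusion_matrix(y[test_idx], clf.predict(Zte), names)
                pooled += cm.counts
                accs.append(accuracy(cm))
        confusion = ConfusionMatrix(names, pooled)
        report["methods"][method] = {
            "mean_accuracy": float(np.mean(accs)),
            "variance": float(np.var(accs)),
            "micro_f1": micro_f1(confusion),
            "macro_f1": macro_f1(confusion),
            "per_fold_accuracy": list(map(float, accs)),
            "confusion": confusion.counts.tolist(),
        }
        logger.info("%s: acc=%.4f micro_f1=%.4f", method,
                    report["methods"][method]["mean_accuracy"],
                    report["methods"][method]["micro_f1"])
    return report
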