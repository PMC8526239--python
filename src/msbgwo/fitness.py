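"""Wrapper fitness: KNN cross-validated accuracy and subset-size trade-off.

A feature mask is scored by restricting the dataset to the selected
columns, running stratified k-fold cross-validation of a k-nearest-
neighbour classifier (Euclidean distance, majority vote), and combining
the mean fold accuracy AvgAcc with the subset size S through the
biobjective fitness

    fit = (1 - alpha) * S / D - alpha * AvgAcc          (minimized)

with alpha = 0.8 by default, i.e. accuracy dominates but every extra
feature costs.  Classification metrics (accuracy, precision, recall,
F-measure) are derived from confusion counts pooled over folds, with the
label coded 1 as the positive class.

Determinism: fold assignment is seeded; neighbour distance ties break
toward the lowest training-sample index; vote ties break toward class 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

#: sentinel fitness for the empty feature subset — finite but strictly
#: larger than any value the biobjective fitness can reach (its range is
#: a subset of (-1, 1) for any alpha in (0, 1)).
EMPTY_MASK_FITNESS = 2.0


@dataclass(frozen=True)
class ConfusionCounts:
    """Raw two-class confusion counts (class 1 is positive)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    selected_features: int


@dataclass(frozen=True)
class FitnessReport:
    """Result of scoring one mask: fitness plus its ingredients."""

    fitness: float
    avg_acc: float
    mask_size: int
    total_features: int


@dataclass(frozen=True)
class FitnessConfig:
    """Fitness-evaluation settings.

    alpha : weight of accuracy vs subset size in (0, 1); default 0.8.
    knn_k : neighbour count; default 5.
    folds : stratified CV folds; default 10.
    cv_seed : seed for the fold shuffle.
    """

    alpha: float = 0.8
    knn_k: int = 5
    folds: int = 10
    cv_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.knn_k < 1:
            raise ValueError(f"knn_k must be >= 1, got {self.knn_k}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")


def fitness_from_accuracy(avg_acc: float, S: int, D: int, alpha: float = 0.8) -> float:
    """Biobjective fitness (1 - alpha) * S / D - alpha * avg_acc.

    Strictly decreasing in accuracy, strictly increasing in subset size;
    lower is better.  Equivalent, up to the constant alpha, to penalizing
    the error rate (1 - avg_acc) instead — the two induce identical
    rankings.
    """
    if S == 0:
        raise ValueError("fitness undefined for the empty feature subset")
    if not 1 <= S <= D:
        raise ValueError(f"subset size S={S} outside [1, D={D}]")
    if not 0.0 <= avg_acc <= 1.0:
        raise ValueError(f"avg_acc must lie in [0, 1], got {avg_acc}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return (1.0 - alpha) * (S / D) - alpha * avg_acc


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and F-measure from raw counts.

    Zero-denominator cases (e.g. no predicted positives) yield 0 with a
    warning rather than an error; ``selected_features`` is not knowable
    from counts alone and is reported as 0 here.
    """
    if counts.total == 0:
        raise ValueError("confusion_metrics requires at least one scored sample")
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        warnings.warn("no predicted positives; precision set to 0", stacklevel=2)
        precision = 0.0
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        warnings.warn("no true positives in labels; recall set to 0", stacklevel=2)
        recall = 0.0
    if precision + recall > 0:
        f_measure = 2.0 * precision * recall / (precision + recall)
    else:
        f_measure = 0.0
    return MetricSet(accuracy, precision, recall, f_measure, selected_features=0)


def _knn_predict(x_train, y_train, x_test, k):
    """Majority-vote KNN with deterministic tie-breaks.

    Distance ties resolve toward the lowest training index (stable
    argsort); vote ties resolve toward class 1.
    """
    dist = cdist(x_test, x_train)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    votes_for_one = y_train[order].sum(axis=1)
    return (2 * votes_for_one >= k).astype(np.int8)


def _stratified_folds(y, n_folds, seed):
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratification error: smallest class has {counts.min()} samples, "
            f"fewer than {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _cv_score(x, y, folds, k):
    fold_accs = []
    tp = tn = fp = fn = 0
    for train_idx, test_idx in folds:
        pred = _knn_predict(x[train_idx], y[train_idx], x[test_idx], k)
        truth = y[test_idx]
        fold_accs.append(float(np.mean(pred == truth)))
        tp += int(np.sum((pred == 1) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    return float(np.mean(fold_accs)), ConfusionCounts(tp, tn, fp, fn)


def knn_cv_accuracy(dataset, mask, cfg: FitnessConfig = FitnessConfig()):
    """Stratified k-fold CV accuracy of KNN on the masked features.

    Returns ``(avg_acc, pooled_counts)`` where ``avg_acc`` is the mean of
    per-fold accuracies and the confusion counts accumulate over all
    held-out folds.

    Raises
    ------
    ValueError
        If the mask selects no features, a class is too small for the
        requested folds, or a training partition is smaller than knn_k.
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("empty feature subset: mask selects no features")
    x = dataset.X[:, mask.astype(bool)]
    y = dataset.y
    folds = _stratified_folds(y, cfg.folds, cfg.cv_seed)
    min_train = min(len(tr) for tr, _ in folds)
    if min_train < cfg.knn_k:
        raise ValueError(
            f"training partitions of {min_train} samples cannot supply "
            f"knn_k={cfg.knn_k} neighbours"
        )
    return _cv_score(x, y, folds, cfg.knn_k)


class MaskEvaluator:
    """Caching fitness evaluator bound to one dataset and config.

    The stratified fold assignment is computed once, so every mask is
    scored against the same partition.  Reports are memoized by mask
    bits: re-evaluating an unchanged wolf is a dictionary hit.  The
    empty mask gets a sentinel worst-fitness report instead of an error
    so the optimizer population survives a zeroed-out wolf.
    """

    def __init__(self, dataset, cfg: FitnessConfig = FitnessConfig()):
        if not dataset.normalized:
            raise ValueError("MaskEvaluator requires a normalized dataset")
        self.dataset = dataset
        self.cfg = cfg
        self._folds = _stratified_folds(dataset.y, cfg.folds, cfg.cv_seed)
        min_train = min(len(tr) for tr, _ in self._folds)
        if min_train < cfg.knn_k:
            raise ValueError(
                f"training partitions of {min_train} samples cannot supply "
                f"knn_k={cfg.knn_k} neighbours"
            )
        self._cache: dict = {}
        self.n_cache_hits = 0

    def __call__(self, dataset, mask) -> FitnessReport:
        if dataset is not self.dataset:
            raise ValueError("evaluator is bound to a different dataset")
        mask = np.ascontiguousarray(np.asarray(mask, dtype=np.int8))
        key = mask.tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            self.n_cache_hits += 1
            return cached
        D = self.dataset.n_features
        S = int(mask.sum())
        if S == 0:
            logger.info("empty mask scored with sentinel fitness %s", EMPTY_MASK_FITNESS)
            report = FitnessReport(EMPTY_MASK_FITNESS, 0.0, 0, D)
        else:
            x = self.dataset.X[:, mask.astype(bool)]
            avg_acc, _ = _cv_score(x, self.dataset.y, self._folds, self.cfg.knn_k)
            fit = fitness_from_accuracy(avg_acc, S, D, self.cfg.alpha)
            report = FitnessReport(fit, avg_acc, S, D)
        self._cache[key] = report
        return report

    def metrics(self, mask) -> MetricSet:
        """Full metric set for a mask from pooled confusion counts."""
        avg_acc, counts = knn_cv_accuracy(self.dataset, mask, self.cfg)
        m = confusion_metrics(counts)
        return MetricSet(
            accuracy=avg_acc,
            precision=m.precision,
            recall=m.recall,
            f_measure=m.f_measure,
            selected_features=int(np.asarray(mask).sum()),
        )


def evaluate_mask(dataset, mask, cfg: FitnessConfig = FitnessConfig()) -> FitnessReport:
    """Score one mask; convenience wrapper over :class:`MaskEvaluator`."""
    return MaskEvaluator(dataset, cfg)(dataset, mask)
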