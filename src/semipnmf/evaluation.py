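"""Evaluation harness: confusion matrices, per-class metrics, and the two
cross-validation protocols used to benchmark semi-supervised classifiers.

``run_leave_one_unlabeled`` hides one sample's label at a time, fits on
all samples with that one unlabeled, and predicts it.
``run_labeled_count_curve`` draws a fixed number of labeled samples per
class, predicts all the rest, and averages accuracy over repeated trials —
the rising accuracy-versus-labels curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data import UNLABELED, ExpressionMatrix, PartialLabelSet
from .factorization import SemiPNMFConfig, fit

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion",
    "class_metrics",
    "run_leave_one_unlabeled",
    "run_labeled_count_curve",
]


@dataclass
class ConfusionMatrix:
    """r × r counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        r = len(self.classes)
        if self.counts.shape != (r, r):
            raise ValueError("counts must be r × r for r class names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    """One-vs-rest sensitivity/specificity per class plus overall accuracy.

    sensitivity_j = TP/(TP+FN), specificity_j = TN/(TN+FP).  A metric with
    a zero denominator is NaN (missing), and macro averages skip missing
    values rather than counting them as zero.  accuracy is the diagonal
    mass as a percentage in [0, 100].
    """

    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: float

    @property
    def macro_sensitivity(self) -> float:
        return float(np.nanmean(self.sensitivity))

    @property
    def macro_specificity(self) -> float:
        return float(np.nanmean(self.specificity))


def confusion(
    true: np.ndarray, pred: np.ndarray, classes: list[str] | int
) -> ConfusionMatrix:
    """Tally counts[i, j] = number of samples with true class i predicted j."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("true and pred must have equal length")
    if isinstance(classes, int):
        classes = [str(i) for i in range(classes)]
    r = len(classes)
    if true.size and (
        true.min() < 0 or true.max() >= r or pred.min() < 0 or pred.max() >= r
    ):
        raise ValueError("class index out of range")
    counts = np.zeros((r, r), dtype=int)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(counts=counts, classes=list(classes))


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Sensitivity, specificity and total accuracy from a confusion matrix."""
    c = cm.counts
    if c.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c).astype(float)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = c.sum() - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    accuracy = 100.0 * tp.sum() / c.sum()
    return ClassMetrics(sensitivity=sens, specificity=spec, accuracy=accuracy)


def _check_full_labels(labels: PartialLabelSet) -> np.ndarray:
    y = labels.assignment
    if (y == UNLABELED).any():
        raise ValueError("every sample must be labeled in the input")
    return y


def run_leave_one_unlabeled(
    data: ExpressionMatrix,
    labels: PartialLabelSet,
    config: SemiPNMFConfig | None = None,
) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Leave-one-unlabeled cross-validation over a fully labeled dataset.

    For each sample in turn, its label is hidden, the model is fit with
    that single sample unlabeled and all others labeled, and its predicted
    class accumulates into the confusion matrix.  Fold f uses seed
    ``config.seed + f`` so the run is deterministic.
    """
    if config is None:
        config = SemiPNMFConfig()
    y = _check_full_labels(labels)
    n = data.n_samples
    r = labels.n_classes
    class_sizes = np.bincount(y, minlength=r)
    for j, sz in enumerate(class_sizes):
        if sz == 1:
            warnings.warn(
                f"class {labels.classes[j]!r} has a single sample; its fold "
                "has no labeled example of that class",
                stacklevel=2,
            )
    true, pred = [], []
    for i in range(n):
        assign = y.copy()
        assign[i] = UNLABELED
        fold_labels = PartialLabelSet(classes=list(labels.classes), assignment=assign)
        res = fit(data, fold_labels, replace(config, seed=config.seed + i))
        pred.append(int(res.predictions()[0]))
        true.append(int(y[i]))
    cm = confusion(np.asarray(true), np.asarray(pred), list(labels.classes))
    return cm, class_metrics(cm)


def run_labeled_count_curve(
    data: ExpressionMatrix,
    labels: PartialLabelSet,
    counts: list[int],
    trials: int = 100,
    config: SemiPNMFConfig | None = None,
) -> dict[int, tuple[float, float]]:
    """Mean (and std) accuracy versus the number of labeled samples per class.

    For each count c, ``trials`` repetitions draw c labeled samples per
    class uniformly without replacement from a seeded generator, fit, and
    score the prediction accuracy over the remaining samples.  Returns
    ``{count: (mean_accuracy_percent, std_accuracy_percent)}``.
    """
    if config is None:
        config = SemiPNMFConfig()
    y = _check_full_labels(labels)
    r = labels.n_classes
    class_sizes = np.bincount(y, minlength=r)
    smallest = int(class_sizes.min()) if r else 0
    out: dict[int, tuple[float, float]] = {}
    for c in counts:
        if c < 1 or c > smallest - 1:
            raise ValueError(
                f"labeled count {c} must be in [1, smallest class size - 1]"
            )
        accs = []
        for t in range(trials):
            rng = np.random.default_rng((config.seed, c, t))
            assign = np.full_like(y, UNLABELED)
            for j in range(r):
                members = np.flatnonzero(y == j)
                chosen = rng.choice(members, size=c, replace=False)
                assign[chosen] = j
            trial_labels = PartialLabelSet(
                classes=list(labels.classes), assignment=assign
            )
            res = fit(data, trial_labels, replace(config, seed=config.seed + t))
            unlabeled = assign == UNLABELED
            correct = res.predictions() == y[unlabeled]
            accs.append(100.0 * float(np.mean(correct)))
        out[c] = (float(np.mean(accs)), float(np.std(accs)))
    return out
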