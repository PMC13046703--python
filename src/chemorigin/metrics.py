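"""Splitting and evaluation: stratified 80/20 split, 5-fold CV, macro metrics.

The evaluation layer mirrors how origin-discrimination models are judged:
a stratified train/test split, stratified k-fold cross-validation inside the
training split, a true × predicted confusion matrix, overall accuracy,
per-class recall / precision / F1, macro-averaged recall and precision
(arithmetic means over classes), a macro-F1 defined as the harmonic mean of
macro-recall and macro-precision, and a macro one-vs-rest AUC on per-class
decision scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .synthesis import ChemTable

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "stratified_split",
    "stratified_kfold",
    "confusion",
    "metrics",
    "macro_f1_from_macros",
    "macro_ovr_auc",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SplitPlan:
    train: np.ndarray
    test: np.ndarray
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test indices overlap")


def stratified_split(table: ChemTable, test_fraction: float = 0.2,
                     seed: int = 0, group_by: str = "region") -> SplitPlan:
    """Disjoint covering train/test split preserving class proportions.

    Per class the test count is round-half-up(n_class × fraction); the rounding
    residue against the global target round-half-up(N × fraction) is then
    spread one sample per class over the largest classes, keeping every class
    within one sample of its exact share.  Deterministic under ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = table.labels(group_by)
    classes = list(dict.fromkeys(y))
    sizes = {c: int((y == c).sum()) for c in classes}
    for c, n in sizes.items():
        if n < 2:
            raise ValueError(f"class {c!r} has only {n} sample(s); cannot split")

    alloc = {c: _round_half_up(sizes[c] * test_fraction) for c in classes}
    target = _round_half_up(len(y) * test_fraction)
    # distribute the rounding residue one sample per class, largest classes
    # first, so every class stays within one sample of its exact share
    by_size = sorted(classes, key=lambda c: (-sizes[c], str(c)))
    i = 0
    while sum(alloc.values()) != target and i < 10 * len(classes):
        c = by_size[i % len(classes)]
        delta = 1 if sum(alloc.values()) < target else -1
        if 0 <= alloc[c] + delta <= sizes[c] - 1:
            alloc[c] += delta
        i += 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        test_idx.extend(idx[: alloc[c]])
        train_idx.extend(idx[alloc[c]:])
    return SplitPlan(np.sort(np.array(train_idx)), np.sort(np.array(test_idx)),
                     test_fraction, seed)


def stratified_kfold(table: ChemTable, k: int = 5, seed: int = 0,
                     group_by: str = "region") -> list[np.ndarray]:
    """k stratified folds (arrays of held-out indices) partitioning the table.

    Classes with fewer than k members trigger scikit-learn's warning but are
    still spread as evenly as the integers allow, so no training fold ever
    loses a class entirely.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    y = table.labels(group_by).astype(str)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y, dtype=float), y)]


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-label rows × predicted-label columns."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k) or (counts < 0).any():
            raise ValueError("counts must be a non-negative square matrix over labels")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, encoding="utf-8")


def confusion(y_true, y_pred, labels: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label arrays differ in length")
    if labels is None:
        labels = sorted(set(y_true))
    unknown = sorted(set(y_pred) - set(labels))
    if unknown:
        raise ValueError(f"predicted labels outside the label set: {unknown}")
    counts = _sk_confusion(y_true, y_pred, labels=list(labels))
    return ConfusionMatrix(tuple(str(l) for l in labels), counts)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    per_class_recall: dict[str, float]
    per_class_precision: dict[str, float]
    per_class_f1: dict[str, float]
    macro_recall: float
    macro_precision: float
    macro_f1: float
    n_classes: int
    warnings: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "n_classes": self.n_classes,
            "per_class_recall": self.per_class_recall,
            "per_class_precision": self.per_class_precision,
            "per_class_f1": self.per_class_f1,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def macro_f1_from_macros(macro_recall: float, macro_precision: float) -> float:
    """Macro-F1: the harmonic mean of macro-recall and macro-precision."""
    s = macro_recall + macro_precision
    return float(2 * macro_recall * macro_precision / s) if s else 0.0


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class R/P/F1 and the three macro quantities from counts.

    Macro-recall and macro-precision are arithmetic means over classes;
    macro-F1 is the harmonic mean of those two macros (not the mean of
    per-class F1).  A class with zero predicted (or true) positives gets
    precision (recall) 0 with a logged warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    notes: list[str] = []
    tp = np.diag(cm.counts).astype(float)
    row = cm.counts.sum(axis=1).astype(float)   # true support (TP + FN)
    col = cm.counts.sum(axis=0).astype(float)   # predicted positives (TP + FP)

    recall, precision, f1 = {}, {}, {}
    for i, lab in enumerate(cm.labels):
        if row[i] == 0:
            notes.append(f"class {lab!r} has no true samples; recall set to 0")
        if col[i] == 0:
            notes.append(f"class {lab!r} has no predicted samples; precision set to 0")
        r = tp[i] / row[i] if row[i] else 0.0
        p = tp[i] / col[i] if col[i] else 0.0
        recall[lab] = float(r)
        precision[lab] = float(p)
        f1[lab] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    for note in notes:
        warnings.warn(note, stacklevel=2)

    macro_r = float(np.mean(list(recall.values())))
    macro_p = float(np.mean(list(precision.values())))
    macro_f1 = macro_f1_from_macros(macro_r, macro_p)
    return MetricsReport(
        accuracy=float(tp.sum() / cm.total),
        per_class_recall=recall, per_class_precision=precision, per_class_f1=f1,
        macro_recall=macro_r, macro_precision=macro_p, macro_f1=float(macro_f1),
        n_classes=len(cm.labels), warnings=tuple(notes),
    )


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-sum (Mann–Whitney) AUC with midrank tie handling."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = rankdata(scores)  # midranks
    rank_sum = float(ranks[positive].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def macro_ovr_auc(scores: np.ndarray, y_true, classes) -> float:
    """Arithmetic mean over classes of the one-vs-rest AUC of each score column.

    ``scores`` has one column per entry of ``classes`` (the classifier's
    ``classes_``).  Classes absent from ``y_true`` are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(str)
    classes = [str(c) for c in classes]
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("score matrix must have one column per class")
    if scores.shape[0] != y_true.size:
        raise ValueError("scores and labels differ in length")
    aucs = []
    for j, c in enumerate(classes):
        positive = y_true == c
        if not positive.any() or positive.all():
            warnings.warn(f"class {c!r} absent from one side of the truth; skipped",
                          stacklevel=2)
            continue
        aucs.append(_binary_auc(scores[:, j], positive))
    if not aucs:
        raise ValueError("no class had both positive and negative samples")
    return float(np.mean(aucs))
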