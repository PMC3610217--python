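"""Confusion-matrix bookkeeping, sensitivity/specificity, and ROC/AUC.

The matrix orientation is rows = class in whose sequences an n-gram occurs,
columns = class the n-gram was assigned to.  Diagonal entries are true
positives; row sum minus the diagonal gives false negatives, column sum
minus the diagonal gives false positives, and everything else is true
negatives.  An assigned n-gram that occurs in no sequence at all is kept in
a separate per-class tally and counted as a false negative of its class.

ROC curves sweep the selection threshold; the AUC is the trapezoidal
integral over the (FPR, TPR) points plus the (0,0) and (1,1) anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError
from .io_formats import LabeledDataset
from .scoring import DiscriminativeNGram


@dataclass
class ConfusionMatrix:
    labels: tuple[str, ...]
    cells: np.ndarray  # rows: occurrence class, columns: assigned class
    unmapped: np.ndarray  # per assigned class: grams occurring nowhere

    def _i(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise DataError(f"unknown class {label!r}") from None

    def tp(self, label: str) -> int:
        i = self._i(label)
        return int(self.cells[i, i])

    def fn(self, label: str) -> int:
        i = self._i(label)
        return int(self.cells[i, :].sum() - self.cells[i, i] + self.unmapped[i])

    def fp(self, label: str) -> int:
        i = self._i(label)
        return int(self.cells[:, i].sum() - self.cells[i, i])

    def tn(self, label: str) -> int:
        total = int(self.cells.sum() + self.unmapped.sum())
        return total - self.tp(label) - self.fn(label) - self.fp(label)


def build_confusion(
    discriminative: Iterable[DiscriminativeNGram], eval_dataset: LabeledDataset
) -> ConfusionMatrix:
    """Presence-based incidence matrix of assigned n-grams over the
    evaluation sequences.

    For an n-gram assigned to class c, each class c' in whose sequences the
    gram occurs at least once contributes one count to cells[c'][c].
    """
    labels = eval_dataset.classes
    index = {c: i for i, c in enumerate(labels)}
    sequences = {
        c: [r.residues for r in recs] for c, recs in eval_dataset.by_class().items()
    }
    cells = np.zeros((len(labels), len(labels)), dtype=np.int64)
    unmapped = np.zeros(len(labels), dtype=np.int64)
    for item in discriminative:
        if item.assigned_class not in index:
            raise DataError(
                f"assigned class {item.assigned_class!r} absent from dataset"
            )
        col = index[item.assigned_class]
        occurred = False
        for c, seqs in sequences.items():
            if any(item.gram in s for s in seqs):
                cells[index[c], col] += 1
                occurred = True
        if not occurred:
            unmapped[col] += 1
    return ConfusionMatrix(labels=labels, cells=cells, unmapped=unmapped)


def sensitivity(cm: ConfusionMatrix, label: str) -> float | None:
    """TP / (TP + FN); None when the denominator is zero (reported as NA)."""
    tp, fn = cm.tp(label), cm.fn(label)
    if tp + fn == 0:
        return None
    return tp / (tp + fn)


def specificity(cm: ConfusionMatrix, label: str) -> float | None:
    """TN / (TN + FP); None when the denominator is zero (reported as NA)."""
    tn, fp = cm.tn(label), cm.fp(label)
    if tn + fp == 0:
        return None
    return tn / (tn + fp)


@dataclass
class RocCurve:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), sorted by FPR
    auc: float


def roc_auc(sweep: Mapping[float, tuple[float, float]] | Sequence[tuple[float, float]]) -> RocCurve:
    """Trapezoidal ROC curve over per-threshold (FPR, TPR) operating points.

    The (0,0) and (1,1) anchors are always included; duplicated points do
    not change the area.
    """
    if isinstance(sweep, Mapping):
        raw = list(sweep.values())
    else:
        raw = list(sweep)
    if not raw:
        raise DataError("ROC needs at least one operating point")
    points = sorted(
        {(float(f), float(t)) for f, t in raw} | {(0.0, 0.0), (1.0, 1.0)}
    )
    fpr = np.array([p[0] for p in points], dtype=float)
    tpr = np.array([p[1] for p in points], dtype=float)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=tuple(points), auc=auc)


def class_operating_point(
    cm: ConfusionMatrix, label: str
) -> tuple[float, float] | None:
    """(FPR, TPR) for one class at one threshold; None when either rate is
    undefined."""
    tpr = sensitivity(cm, label)
    spec = specificity(cm, label)
    if tpr is None or spec is None:
        return None
    return (1.0 - spec, tpr)
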