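"""Evaluation and wrapper-fitness metrics.

All per-class scores are one-vs-rest over the multiclass confusion matrix:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), Matthews correlation
coefficient and its [0,1]-normalized form (MCC+1)/2.  Two composite scores
drive the band-selection wrappers:

* ``fom`` — a pairwise balance score over per-class accuracies,
  FoM = (1/2) * mean over class pairs of (ACCi + ACCj) / (|ACCi - ACCj| + 1),
  which rewards uniformly good classes rather than a high average carried by
  one easy class;
* ``penalized`` — (1 - base) * (1 + lambda/lambda_max), a minimized fitness
  that trades classification error against the fraction of bands kept.

Note on specificity: the source formulation of these metrics prints the
overall-accuracy formula twice; specificity here is the standard TN/(TN+FP),
which is what the reported per-class results require.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.metrics import confusion_matrix

from .types import N_CLASSES


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN per class, plus the full multiclass matrix."""

    matrix: np.ndarray  # n_classes x n_classes, rows = truth
    n_classes: int

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def tp(self, c: int) -> int:
        return int(self.matrix[c, c])

    def fn(self, c: int) -> int:
        return int(self.matrix[c].sum() - self.matrix[c, c])

    def fp(self, c: int) -> int:
        return int(self.matrix[:, c].sum() - self.matrix[c, c])

    def tn(self, c: int) -> int:
        return self.total - self.tp(c) - self.fn(c) - self.fp(c)


def confusion(true_labels, predicted_labels, n_classes: int = N_CLASSES) -> ConfusionCounts:
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size == 0:
        raise ValueError("empty label vectors")
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must align")
    if true_labels.max() >= n_classes or predicted_labels.max() >= n_classes:
        raise ValueError("label exceeds n_classes")
    mat = confusion_matrix(true_labels, predicted_labels, labels=np.arange(n_classes))
    return ConfusionCounts(mat, n_classes)


def overall_accuracy(c: ConfusionCounts) -> float:
    return float(np.trace(c.matrix) / c.total)


def sensitivity(c: ConfusionCounts, class_id: int) -> float:
    denom = c.tp(class_id) + c.fn(class_id)
    return c.tp(class_id) / denom if denom else float("nan")


def specificity(c: ConfusionCounts, class_id: int) -> float:
    denom = c.tn(class_id) + c.fp(class_id)
    return c.tn(class_id) / denom if denom else float("nan")


def acc_per_class(c: ConfusionCounts, class_id: int) -> float:
    """Per-class accuracy TP/(TP+FN); identical to sensitivity by definition."""
    return sensitivity(c, class_id)


def mcc(c: ConfusionCounts, class_id: int) -> float:
    """One-vs-rest Matthews correlation coefficient in [-1, 1].

    A zero factor under the root makes the coefficient undefined; the common
    convention MCC = 0 is used in that case.
    """
    tp, fp, tn, fn = c.tp(class_id), c.fp(class_id), c.tn(class_id), c.fn(class_id)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom2)


def mcc_norm(c: ConfusionCounts, class_id: int) -> float:
    """MCC rescaled to [0, 1]: (MCC + 1) / 2."""
    return (mcc(c, class_id) + 1.0) / 2.0


def fom(accs) -> float:
    """Pairwise balanced-accuracy figure of merit over per-class accuracies."""
    accs = np.asarray(accs, dtype=float)
    if accs.size < 2:
        raise ValueError("FoM needs at least two class accuracies")
    if np.any((accs < 0) | (accs > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    terms = [
        (accs[i] + accs[j]) / (abs(accs[i] - accs[j]) + 1.0)
        for i, j in combinations(range(accs.size), 2)
    ]
    n_pairs = accs.size * (accs.size - 1) // 2
    return 0.5 * sum(terms) / n_pairs


@dataclass(frozen=True)
class FitnessValue:
    """Minimized wrapper fitness with its band-count bookkeeping."""

    value: float
    base_metric: str  # "oa_p" | "fom_p"
    n_selected: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_selected > self.n_total:
            raise ValueError("selected band count exceeds total")
        if self.value < 0:
            raise ValueError("fitness must be nonnegative")


def penalized(
    base: float,
    n_selected: int,
    n_total: int,
    which: str = "oa_p",
    form: str = "product",
) -> FitnessValue:
    """Band-count-penalized error: (1 - base) * (1 + lambda/lambda_max).

    ``form="quotient"`` computes (1 - base) / (1 + lambda/lambda_max) instead,
    provided only for reproduction studies — it rewards larger subsets and is
    not used by default.
    """
    if not 0 <= base <= 1:
        raise ValueError("base metric must lie in [0, 1]")
    if not 1 <= n_selected <= n_total:
        raise ValueError("need 1 <= n_selected <= n_total")
    ratio = 1.0 + n_selected / n_total
    err = 1.0 - base
    value = err * ratio if form == "product" else err / ratio
    return FitnessValue(value, which, n_selected, n_total)


@dataclass
class MetricsReport:
    """Per-fold evaluation summary (all proportions in [0, 1])."""

    oa: float
    sensitivity: list[float]
    specificity: list[float]
    mcc: list[float]
    mcc_norm: list[float]
    fom: float
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        return {
            "oa": self.oa,
            "sensitivity": list(self.sensitivity),
            "specificity": list(self.specificity),
            "mcc": list(self.mcc),
            "mcc_norm": list(self.mcc_norm),
            "fom": self.fom,
        }


def report_from_labels(true_labels, predicted_labels, n_classes: int = N_CLASSES) -> MetricsReport:
    """Compute the full per-fold report from label vectors."""
    c = confusion(true_labels, predicted_labels, n_classes)
    sens = [sensitivity(c, k) for k in range(n_classes)]
    spec = [specificity(c, k) for k in range(n_classes)]
    present = [s for s in sens if not np.isnan(s)]
    return MetricsReport(
        oa=overall_accuracy(c),
        sensitivity=sens,
        specificity=spec,
        mcc=[mcc(c, k) for k in range(n_classes)],
        mcc_norm=[mcc_norm(c, k) for k in range(n_classes)],
        fom=fom(present) if len(present) >= 2 else float("nan"),
        counts=c,
    )


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Mean and standard deviation across folds, NaN-aware."""
    if not reports:
        raise ValueError("no reports to aggregate")

    def stat(values):
        arr = np.asarray(values, dtype=float)
        return {"mean": float(np.nanmean(arr)), "std": float(np.nanstd(arr))}

    out = {
        "oa": stat([r.oa for r in reports]),
        "fom": stat([r.fom for r in reports]),
        "n_folds": len(reports),
    }
    n_classes = len(reports[0].sensitivity)
    for name in ("sensitivity", "specificity", "mcc", "mcc_norm"):
        out[name] = [
            stat([getattr(r, name)[k] for r in reports]) for k in range(n_classes)
        ]
    return out
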