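"""One-vs-rest ROC analysis of classifier posterior scores.

For each group, its posterior probability is treated as a diagnostic score
with that group as the positive state and the other two pooled as negative.
The ROC curve sweeps every distinct score as a threshold (positive iff
score >= threshold), the area under it is computed by the trapezoidal rule
(equal to the Mann-Whitney U fraction with ties counted half), and the
optimal operating point maximizes the Youden index J = sensitivity +
specificity - 1, resolving ties toward the most sensitive (lowest) cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ROCCurve", "ROCReport", "roc_curve", "youden_optimal", "roc_report"]


@dataclass
class ROCCurve:
    positive_class: str
    thresholds: np.ndarray  # descending; +inf sentinel first
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    youden_j: float = field(init=False)
    optimal_cutoff: float = field(init=False)
    optimal_sensitivity: float = field(init=False)
    optimal_specificity: float = field(init=False)

    def __post_init__(self) -> None:
        j = self.sensitivity - self.one_minus_specificity
        best = float(j.max())
        # ties toward the most sensitive operating point = lowest threshold;
        # thresholds are descending so take the LAST attaining index
        ties = np.flatnonzero(np.isclose(j, best, rtol=0.0, atol=1e-12))
        if ties.size > 1:
            logger.info(
                "Youden index tied at %d thresholds for class %s; using the most sensitive",
                ties.size,
                self.positive_class,
            )
        i = int(ties[-1])
        self.youden_j = best
        self.optimal_cutoff = float(self.thresholds[i])
        self.optimal_sensitivity = float(self.sensitivity[i])
        self.optimal_specificity = float(1.0 - self.one_minus_specificity[i])


def roc_curve(scores: np.ndarray, labels: np.ndarray, positive_class: str) -> ROCCurve:
    """ROC curve of a score for one positive class.

    Every distinct score acts as a threshold; tied scores collapse into one
    step.  A +inf sentinel pins the (0, 0) endpoint; the lowest observed
    score yields (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative observation")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    pos_sorted = pos[order].astype(float)
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    last_of_block = np.r_[distinct, s_sorted.size - 1]
    tp = np.cumsum(pos_sorted)[last_of_block]
    fp = np.cumsum(1.0 - pos_sorted)[last_of_block]
    thresholds = np.r_[np.inf, s_sorted[last_of_block]]
    sens = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(
        positive_class=positive_class,
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=auc,
    )


def youden_optimal(curve: ROCCurve) -> tuple[float, float, float, float]:
    """(cutoff, sensitivity, specificity, J) at the Youden-optimal threshold."""
    return (
        curve.optimal_cutoff,
        curve.optimal_sensitivity,
        curve.optimal_specificity,
        curve.youden_j,
    )


@dataclass
class ROCReport:
    """Per-class one-vs-rest curves plus their arithmetic averages."""

    curves: dict[str, ROCCurve]

    @property
    def average_auc(self) -> float:
        return float(np.mean([c.auc for c in self.curves.values()]))

    @property
    def average_optimal_sensitivity(self) -> float:
        return float(np.mean([c.optimal_sensitivity for c in self.curves.values()]))

    @property
    def average_one_minus_specificity(self) -> float:
        return float(np.mean([1.0 - c.optimal_specificity for c in self.curves.values()]))

    def to_rows(self) -> list[dict]:
        rows = [
            {
                "class": name,
                "auc": c.auc,
                "optimal_sensitivity": c.optimal_sensitivity,
                "one_minus_optimal_specificity": 1.0 - c.optimal_specificity,
                "optimal_cutoff": c.optimal_cutoff,
            }
            for name, c in self.curves.items()
        ]
        rows.append(
            {
                "class": "Average",
                "auc": self.average_auc,
                "optimal_sensitivity": self.average_optimal_sensitivity,
                "one_minus_optimal_specificity": self.average_one_minus_specificity,
                "optimal_cutoff": None,
            }
        )
        return rows


def roc_report(posteriors: np.ndarray, labels: np.ndarray, class_names: list[str]) -> ROCReport:
    """One-vs-rest ROC report from a posterior matrix (columns follow class_names)."""
    posteriors = np.atleast_2d(np.asarray(posteriors, dtype=float))
    labels = np.asarray(labels)
    present = set(labels)
    missing = [c for c in class_names if c not in present]
    if missing:
        raise ValueError(f"classes {missing} have no observations")
    curves = {
        name: roc_curve(posteriors[:, k], labels, name) for k, name in enumerate(class_names)
    }
    return ROCReport(curves=curves)
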