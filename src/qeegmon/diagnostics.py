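"""ROC calibration and diagnostic-accuracy statistics.

The decline cut-off for each (channel, metric, time point) cell is
calibrated by an empirical ROC against the TCD gold standard: every
observed percent change is a candidate threshold, a case is called
positive when its change is at or below the threshold, and the optimal
cut-off maximizes the Youden index J = sensitivity + specificity - 1
(ties broken toward higher sensitivity — a monitor should not miss
ischemia). The AUC is the trapezoidal area under the empirical curve and
its 95% CI uses the Hanley-McNeil standard error. Agreement with TCD is
summarized by sensitivity/specificity/PPV/NPV and Cohen's kappa from the
2x2 contingency ("four-grid") table; a table can also be reconstructed
exactly from published sensitivity/specificity and the group sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RocResult", "ConfusionTable", "AccuracySummary",
    "roc_calibrate", "confusion_from_predictions", "accuracy_summary",
    "reconstruct_confusion", "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from the floor (0.5 -> 1), as clinical
    statistics packages print, rather than banker's rounding."""
    factor = 10.0 ** decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass
class RocResult:
    thresholds: np.ndarray     # candidate cut-offs (observed pct changes)
    sensitivities: np.ndarray  # fraction in [0, 1], aligned with thresholds
    specificities: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    optimal_cutoff: float      # percent (negative = decline)
    youden_j: float


@dataclass
class ConfusionTable:
    """2x2 counts of prediction vs gold standard."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class AccuracySummary:
    """Sensitivity/specificity/predictive values (percent) and Cohen's kappa.

    Metrics whose denominator is zero are returned as NaN.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float

    def rounded(self) -> "AccuracySummary":
        """Printed precision: percents to 1 decimal, kappa to 3 (half-up)."""
        r = lambda v, d: v if math.isnan(v) else round_half_up(v, d)
        return AccuracySummary(
            r(self.sensitivity, 1), r(self.specificity, 1),
            r(self.ppv, 1), r(self.npv, 1), r(self.kappa, 3),
        )


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """95% CI for the AUC via the Hanley-McNeil standard-error formula."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    return (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))


def roc_calibrate(pct_changes, gold_labels) -> RocResult:
    """Calibrate a decline cut-off from percent changes and gold labels.

    Parameters
    ----------
    pct_changes
        Signed percent changes from baseline (negative = decline).
    gold_labels
        Boolean gold-standard ischemia labels, aligned with ``pct_changes``.
    """
    scores = np.asarray(pct_changes, dtype=float)
    gold = np.asarray(gold_labels, dtype=bool)
    if scores.shape != gold.shape or scores.ndim != 1:
        raise ValueError("pct_changes and gold_labels must be equal-length 1-D")
    n_pos = int(gold.sum())
    n_neg = int((~gold).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC calibration requires both gold classes present")

    thresholds = np.unique(scores)  # ascending; positive iff score <= t
    sens = np.array([(scores[gold] <= t).mean() for t in thresholds])
    spec = np.array([(scores[~gold] > t).mean() for t in thresholds])

    # empirical curve from (0,0) to (1,1); FPR ascending with thresholds
    fpr = np.concatenate(([0.0], 1 - spec, [1.0]))
    tpr = np.concatenate(([0.0], sens, [1.0]))
    auc = float(np.trapezoid(tpr, fpr))

    j = sens + spec - 1
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    # ties: prefer higher sensitivity, then higher specificity
    order = sorted(candidates, key=lambda i: (sens[i], spec[i]), reverse=True)
    best = order[0]

    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci95=_hanley_mcneil_ci(auc, n_pos, n_neg),
        optimal_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def confusion_from_predictions(preds, gold) -> ConfusionTable:
    """Exact 2x2 counts from aligned prediction and gold-label sequences."""
    preds = np.asarray(preds, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    if preds.shape != gold.shape:
        raise ValueError("predictions and gold labels differ in length")
    if gold.all() or not gold.any():
        raise ValueError("need at least one of each gold class")
    return ConfusionTable(
        tp=int((preds & gold).sum()),
        fn=int((~preds & gold).sum()),
        fp=int((preds & ~gold).sum()),
        tn=int((~preds & ~gold).sum()),
    )


def accuracy_summary(t: ConfusionTable) -> AccuracySummary:
    """Sensitivity, specificity, PPV, NPV (percent) and Cohen's kappa.

    Kappa is the chance-corrected agreement
    ``(p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = (tp + tn) / n`` and chance agreement
    ``p_e = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)] / n^2``.
    """
    if t.n == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    p_o = (t.tp + t.tn) / t.n
    p_e = ((t.tp + t.fp) * (t.tp + t.fn)
           + (t.fn + t.tn) * (t.fp + t.tn)) / (t.n * t.n)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1 - p_e)

    return AccuracySummary(
        sensitivity=ratio(t.tp, t.tp + t.fn),
        specificity=ratio(t.tn, t.tn + t.fp),
        ppv=ratio(t.tp, t.tp + t.fp),
        npv=ratio(t.tn, t.tn + t.fn),
        kappa=kappa,
    )


def reconstruct_confusion(sens: float, spec: float,
                          n_pos: int, n_neg: int) -> ConfusionTable:
    """Recover the 2x2 table behind published sensitivity/specificity.

    With the ischemic/non-ischemic group sizes known, the true-positive and
    true-negative counts are the half-up-rounded products
    ``sens/100 * n_pos`` and ``spec/100 * n_neg``; the remaining cells
    follow by subtraction.
    """
    if not (0 <= sens <= 100 and 0 <= spec <= 100):
        raise ValueError("sensitivity and specificity must be in [0, 100]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("group sizes must be positive")
    tp = int(round_half_up(sens / 100.0 * n_pos))
    tn = int(round_half_up(spec / 100.0 * n_neg))
    fn, fp = n_pos - tp, n_neg - tn
    if fn < 0 or fp < 0:
        raise ValueError("inconsistent inputs: reconstructed count negative")
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)
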