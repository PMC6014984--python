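"""Gate-based classification metrics and ROC analysis for co-culture data.

Events are partitioned on the EBFP2 × mKate2 plane into three regions:
L (left; EBFP2 below the transfection threshold, excluded as
under-transfected), RT (right-top; mKate2 at or above the output
threshold, classified as the marker-positive cell type) and RB
(right-bottom, classified marker-negative).  With + / − denoting the true
lineage (simulation label, or an EYFP gate):

* sensitivity (true positive rate) = RT⁺ / (RT⁺ + RB⁺)
* specificity (true negative rate) = RB⁻ / (RB⁻ + RT⁻)
* accuracy = (RT⁺ + RB⁻) / (RT⁺ + RT⁻ + RB⁺ + RB⁻)

ROC curves sweep the mKate2 threshold (conventionally fixed at 10² a.u.
for single-threshold scores) and are summarized by trapezoidal AUC;
replicate curves sharing a threshold grid are combined by threshold
averaging (pointwise mean ± SD of FPR and TPR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import validate_events

#: single-threshold scores use a fixed output threshold of 10^2 a.u.
DEFAULT_MKATE2_THRESHOLD = 100.0


@dataclass(frozen=True)
class GateCounts:
    """Event counts per gate region, split by true lineage."""

    rt_pos: int
    rt_neg: int
    rb_pos: int
    rb_neg: int
    l: int

    @property
    def total(self) -> int:
        return self.rt_pos + self.rt_neg + self.rb_pos + self.rb_neg + self.l


@dataclass(frozen=True)
class ClassifierScore:
    """Sensitivity/specificity/accuracy (NaN when undefined) with gate counts."""

    sensitivity: float
    specificity: float
    accuracy: float
    counts: GateCounts
    ebfp2_threshold: float
    mkate2_threshold: float


@dataclass(frozen=True)
class ROCCurve:
    """ROC points (FPR, TPR) per threshold, with trapezoidal AUC.

    ``fpr_sd``/``tpr_sd`` carry the per-threshold spread when the curve is
    a threshold average over replicates.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    fpr_sd: np.ndarray | None = None
    tpr_sd: np.ndarray | None = None


def _positive_mask(events: pd.DataFrame, positive_label: str | None,
                   eyfp_threshold: float | None) -> np.ndarray:
    """True-lineage mask: simulation label when available, else EYFP gate."""
    if positive_label is not None:
        if "lineage_label" not in events.columns:
            raise ValueError("positive_label given but events carry no "
                             "lineage_label column")
        return np.asarray(events["lineage_label"] == positive_label)
    if eyfp_threshold is not None:
        if "eyfp" not in events.columns:
            raise ValueError("eyfp_threshold given but events carry no "
                             "eyfp column")
        return np.asarray(events["eyfp"], dtype=float) >= eyfp_threshold
    raise ValueError("need positive_label or eyfp_threshold to define the "
                     "true lineage")


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def gate_counts(events: pd.DataFrame, ebfp2_threshold: float,
                mkate2_threshold: float,
                positive_label: str | None = None,
                eyfp_threshold: float | None = None) -> GateCounts:
    """Count events per RT/RB/L region split by true lineage."""
    validate_events(events)
    pos = _positive_mask(events, positive_label, eyfp_threshold)
    ebfp2 = np.asarray(events["ebfp2"], dtype=float)
    mkate2 = np.asarray(events["mkate2"], dtype=float)
    left = ebfp2 < ebfp2_threshold
    rt = ~left & (mkate2 >= mkate2_threshold)
    rb = ~left & ~rt
    return GateCounts(
        rt_pos=int(np.sum(rt & pos)), rt_neg=int(np.sum(rt & ~pos)),
        rb_pos=int(np.sum(rb & pos)), rb_neg=int(np.sum(rb & ~pos)),
        l=int(np.sum(left)))


def score_from_counts(counts: GateCounts, ebfp2_threshold: float,
                      mkate2_threshold: float) -> ClassifierScore:
    """Apply the metric formulas to gate counts (NaN on a zero denominator)."""
    classified = counts.rt_pos + counts.rt_neg + counts.rb_pos + counts.rb_neg
    return ClassifierScore(
        sensitivity=_ratio(counts.rt_pos, counts.rt_pos + counts.rb_pos),
        specificity=_ratio(counts.rb_neg, counts.rb_neg + counts.rt_neg),
        accuracy=_ratio(counts.rt_pos + counts.rb_neg, classified),
        counts=counts, ebfp2_threshold=ebfp2_threshold,
        mkate2_threshold=mkate2_threshold)


def gate_and_score(events: pd.DataFrame, ebfp2_threshold: float,
                   mkate2_threshold: float = DEFAULT_MKATE2_THRESHOLD,
                   positive_label: str | None = None,
                   eyfp_threshold: float | None = None) -> ClassifierScore:
    """Gate events and compute sensitivity, specificity and accuracy.

    Events with EBFP2 below ``ebfp2_threshold`` fall in L and are excluded
    from all metrics; among the rest, mKate2 ≥ ``mkate2_threshold`` puts an
    event in RT (classified marker-positive), otherwise RB.
    """
    counts = gate_counts(events, ebfp2_threshold, mkate2_threshold,
                         positive_label, eyfp_threshold)
    return score_from_counts(counts, ebfp2_threshold, mkate2_threshold)


def roc_curve(events: pd.DataFrame, ebfp2_threshold: float, thresholds,
              positive_label: str | None = None,
              eyfp_threshold: float | None = None) -> ROCCurve:
    """ROC over a grid of mKate2 thresholds, with (0,0)/(1,1) anchors.

    AUC is computed by the trapezoid rule after sorting points by FPR.
    Requires both lineages to be present after the L exclusion.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size < 2:
        raise ValueError("need >= 2 thresholds")
    validate_events(events)
    pos = _positive_mask(events, positive_label, eyfp_threshold)
    ebfp2 = np.asarray(events["ebfp2"], dtype=float)
    mkate2 = np.asarray(events["mkate2"], dtype=float)
    keep = ebfp2 >= ebfp2_threshold
    n_pos = int(np.sum(keep & pos))
    n_neg = int(np.sum(keep & ~pos))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both lineages must be present after the L exclusion")
    tpr = np.array([np.sum(keep & pos & (mkate2 >= t)) / n_pos
                    for t in thresholds])
    fpr = np.array([np.sum(keep & ~pos & (mkate2 >= t)) / n_neg
                    for t in thresholds])
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr,
                    auc=_auc(fpr, tpr))


def _auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    x = np.concatenate([[0.0], fpr, [1.0]])
    y = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def threshold_average(rocs: list[ROCCurve]) -> ROCCurve:
    """Average replicate ROC curves pointwise at shared thresholds.

    Returns the mean (FPR, TPR) per threshold with sample-SD error bars
    and the AUC of the mean curve.  All replicates must share one
    threshold grid.
    """
    if not rocs:
        raise ValueError("need at least one ROC curve")
    grid = rocs[0].thresholds
    for r in rocs[1:]:
        if r.thresholds.size != grid.size or not np.allclose(r.thresholds, grid):
            raise ValueError("replicates must share one threshold grid")
    fpr = np.stack([r.fpr for r in rocs])
    tpr = np.stack([r.tpr for r in rocs])
    mean_fpr = fpr.mean(axis=0)
    mean_tpr = tpr.mean(axis=0)
    ddof = 1 if len(rocs) > 1 else 0
    return ROCCurve(thresholds=grid, fpr=mean_fpr, tpr=mean_tpr,
                    auc=_auc(mean_fpr, mean_tpr),
                    fpr_sd=fpr.std(axis=0, ddof=ddof),
                    tpr_sd=tpr.std(axis=0, ddof=ddof))
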