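"""Benchmark metrics for contact prediction from coevolution scores.

From a confusion table (TP, FP, TN, FN) the standard operating-point
metrics are

    TPR = TP / (TP + FN)                       (power, recall)
    FPR = FP / (FP + TN)
    PPV = TP / (TP + FP)                       (precision)
    F1  = 2 * PPV * TPR / (TPR + PPV)
    phi = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

Undefined ratios (zero denominators) are reported as NaN rather than 0 so
they drop out of aggregated medians.  Threshold-independent summaries
(auROC by trapezoid, auPR by precision steps, f_max, phi_max) sweep all
distinct score thresholds; tied values are predicted together in blocks.

FPR-controlled operating points use a strict bound (empirical FPR < alpha)
and choose the largest prediction set that still satisfies it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import EvaluationError


@dataclass
class ConfusionTable:
    """Prediction counts at one threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class OperatingPoint:
    """Metrics at one threshold; NaN marks undefined ratios."""

    threshold: float
    tpr: float
    fpr: float
    ppv: float
    f1: float
    phi: float


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(ct: ConfusionTable, threshold: float = float("nan")) -> OperatingPoint:
    """Operating-point metrics from a confusion table."""
    tp, fp, tn, fn = ct.tp, ct.fp, ct.tn, ct.fn
    tpr = _safe_div(tp, tp + fn)
    fpr = _safe_div(fp, fp + tn)
    ppv = _safe_div(tp, tp + fp)
    if np.isnan(tpr) or np.isnan(ppv) or (tpr + ppv) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * ppv * tpr / (tpr + ppv)
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    phi = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else float("nan")
    return OperatingPoint(threshold, tpr, fpr, ppv, f1, float(phi))


def _oriented(values: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "higher":
        return values
    if orientation == "lower":
        return -values
    raise ValueError("orientation must be 'higher' or 'lower'")


def _clean(values, labels, orientation) -> tuple[np.ndarray, np.ndarray]:
    v = _oriented(np.asarray(values, dtype=float).ravel(), orientation)
    y = np.asarray(labels).ravel().astype(bool)
    ok = ~np.isnan(v)
    if not ok.any():
        raise EvaluationError("no unmasked cells to evaluate")
    return v[ok], y[ok]


def confusion(
    values, labels, threshold: float, orientation: str = "higher"
) -> ConfusionTable:
    """Counts with positives predicted at oriented value >= threshold.

    For P-values pass ``orientation="lower"`` and the cutoff on the
    original scale (predict positive iff P <= threshold).
    """
    v, y = _clean(values, labels, orientation)
    thr = threshold if orientation == "higher" else -threshold
    pred = v >= thr
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    return ConfusionTable(tp, fp, tn, fn)


def _threshold_sweep(v: np.ndarray, y: np.ndarray):
    """Cumulative TP/FP at distinct-value block boundaries, strongest first."""
    order = np.argsort(-v, kind="stable")
    v_sorted = v[order]
    y_sorted = y[order]
    boundary = np.r_[v_sorted[1:] != v_sorted[:-1], True]
    idx = np.nonzero(boundary)[0]
    cum_tp = np.cumsum(y_sorted)[idx].astype(float)
    cum_fp = (idx + 1) - cum_tp
    return v_sorted[idx], cum_tp, cum_fp


@dataclass
class CurveResult:
    """ROC/PR curves plus their threshold-independent summaries."""

    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    thresholds: np.ndarray
    auroc: float
    aupr: float
    f_max: float
    phi_max: float


def roc_pr_curves(values, labels, orientation: str = "higher") -> CurveResult:
    """Full threshold sweep with auROC, auPR, f_max and phi_max.

    auROC integrates the ROC curve by trapezoid (equivalent to the
    Mann-Whitney U probability); auPR uses precision steps, i.e. the sum
    of precision * recall-increment over threshold blocks, without linear
    interpolation between PR points.
    """
    v, y = _clean(values, labels, orientation)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes are required for ROC/PR curves")
    thr, cum_tp, cum_fp = _threshold_sweep(v, y)
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    recall = cum_tp / n_pos
    precision = cum_tp / (cum_tp + cum_fp)
    aupr = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
        tn = n_neg - cum_fp
        fn = n_pos - cum_tp
        denom = (cum_tp + fn) * (tn + cum_fp) * (cum_tp + cum_fp) * (tn + fn)
        phi = np.where(denom > 0, (cum_tp * tn - cum_fp * fn) / np.sqrt(denom), np.nan)
    f_max = float(np.nanmax(f1))
    phi_max = float(np.nanmax(phi))
    return CurveResult(fpr, tpr, recall, precision, thr, auroc, aupr, f_max, phi_max)


def power_at_fpr(
    values, labels, alpha: float, orientation: str = "higher"
) -> OperatingPoint:
    """Operating point at the most permissive threshold with FPR < alpha.

    The bound is strict and tied values are predicted in whole blocks;
    among the blocks satisfying the bound the largest prediction set is
    chosen.  If even the strictest non-empty block violates the bound the
    all-negative point is returned with a warning.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    v, y = _clean(values, labels, orientation)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_neg == 0:
        raise EvaluationError("FPR control requires at least one negative")
    thr, cum_tp, cum_fp = _threshold_sweep(v, y)
    ok = (cum_fp / n_neg) < alpha
    if not ok.any():
        warnings.warn("no threshold achieves the FPR bound; returning the all-negative point")
        return metrics(ConfusionTable(0, 0, n_neg, n_pos), float("inf"))
    k = np.nonzero(ok)[0][-1]  # most permissive block under the bound
    tp = int(cum_tp[k])
    fp = int(cum_fp[k])
    ct = ConfusionTable(tp, fp, n_neg - fp, n_pos - tp)
    return metrics(ct, float(thr[k]))


def nominal_fpr(pvalues, labels, alpha: float) -> tuple[float, float]:
    """Realized FPR among labeled negatives at cutoff P <= alpha.

    Returns ``(nominal, nominal / alpha)``; a well-calibrated null gives a
    ratio near 1.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    ok = ~np.isnan(p)
    neg = ok & ~y
    if not neg.any():
        raise EvaluationError("no labeled negatives")
    nominal = float((p[neg] <= alpha).mean())
    return nominal, nominal / alpha


def entropy_stratified_eval(
    values,
    labels,
    entropies_A: np.ndarray,
    entropies_B: np.ndarray,
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    orientation: str = "higher",
) -> dict[tuple[str, str], float]:
    """Evaluate a metric within the four median-entropy strata.

    Column pairs are split by (above/below median H_A) x (above/below
    median H_B); medians are per protein over unmasked columns and ties go
    to "below".  ``metric_fn(values, labels)`` is called on each group's
    oriented values; empty or one-class groups yield NaN.
    """
    v = _oriented(np.asarray(values, dtype=float), orientation)
    y = np.asarray(labels).astype(bool)
    hA = np.asarray(entropies_A, dtype=float)
    hB = np.asarray(entropies_B, dtype=float)
    if v.shape != (hA.size, hB.size) or y.shape != v.shape:
        raise ValueError("shape mismatch between values, labels and entropies")
    medA = np.nanmedian(hA)
    medB = np.nanmedian(hB)
    groupA = np.where(hA > medA, "high", "low")
    groupB = np.where(hB > medB, "high", "low")
    out: dict[tuple[str, str], float] = {}
    for ga in ("low", "high"):
        for gb in ("low", "high"):
            sel = np.ix_(groupA == ga, groupB == gb)
            vv, yy = v[sel].ravel(), y[sel].ravel()
            keep = ~np.isnan(vv)
            vv, yy = vv[keep], yy[keep]
            if vv.size == 0 or yy.all() or not yy.any():
                out[(ga, gb)] = float("nan")
            else:
                out[(ga, gb)] = float(metric_fn(vv, yy))
    return out
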