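"""Method-agreement statistics for calcium-score evaluation.

Covers the comparisons used to judge an automated scorer against a
reference reading: risk-category confusion matrices with accuracy and
unweighted Cohen's kappa, binary calcium-detection metrics (category 0,
score < 1, is "absent"; everything else "present"), Bland-Altman limits
of agreement, Pearson correlation, and the two-sample Kolmogorov-Smirnov
test on score distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class ConfusionMatrix:
    """Rows are ground truth, columns are prediction."""

    counts: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] < 2:
            raise ValueError("need at least 2 categories")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.counts.sum() < 1:
            raise ValueError("empty confusion matrix")
        if not self.labels:
            self.labels = list(range(self.counts.shape[0]))

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class AgreementReport:
    accuracy: float
    kappa: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ba_mean_diff: float
    ba_loa_low: float
    ba_loa_high: float
    pearson_r: float
    ks_d: float
    ks_p: float

    def to_dict(self) -> dict:
        return {k: (None if v is not None and isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.__dict__.items()}


def confusion(truth: Sequence[int], pred: Sequence[int], k: int) -> ConfusionMatrix:
    """K x K confusion counts from paired category lists."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.min() < 0 or truth.max() >= k or pred.min() < 0 or pred.max() >= k:
        raise ValueError(f"categories outside [0, {k})")
    counts = np.bincount(truth * k + pred, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of exact category agreement (trace / total)."""
    return float(np.trace(cm.counts) / cm.n)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa from the table's marginals."""
    n = cm.n
    p_o = np.trace(cm.counts) / n
    rows = cm.counts.sum(axis=1) / n
    cols = cm.counts.sum(axis=0) / n
    p_e = float(rows @ cols)
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("kappa undefined: chance agreement is 1 (degenerate marginals)")
    return float((p_o - p_e) / (1.0 - p_e))


def detection_metrics(cm: ConfusionMatrix, absent_category: int = 0) -> dict[str, float]:
    """Binary presence/absence metrics from a category confusion matrix.

    Truth/prediction are binarized as present (category != absent) vs
    absent.  Ratios with zero denominators are returned as NaN with a
    warning.
    """
    k = cm.counts.shape[0]
    if not 0 <= absent_category < k:
        raise ValueError("absent_category out of range")
    present = np.arange(k) != absent_category
    tp = int(cm.counts[np.ix_(present, present)].sum())
    fn = int(cm.counts[np.ix_(present, ~present)].sum())
    fp = int(cm.counts[np.ix_(~present, present)].sum())
    tn = int(cm.counts[np.ix_(~present, ~present)].sum())

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    return {
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "ppv": ratio(tp, tp + fp, "ppv"),
        "npv": ratio(tn, tn + fn, "npv"),
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def bland_altman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Mean difference and 1.96-SD limits of agreement of x - y.

    The SD uses the n-1 (sample) denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def agreement_report(truth_total: Sequence[float], pred_total: Sequence[float],
                     truth_cat: Sequence[int], pred_cat: Sequence[int],
                     k: int = 5) -> tuple[AgreementReport, ConfusionMatrix]:
    """Full agreement suite between a reference and a predicted scoring."""
    cm = confusion(truth_cat, pred_cat, k)
    det = detection_metrics(cm)
    mean_diff, lo, hi = bland_altman(pred_total, truth_total)
    try:
        r = pearson_r(truth_total, pred_total)
    except ValueError:
        r = float("nan")
    ks_d, ks_p = ks_two_sample(truth_total, pred_total)
    try:
        kappa = cohen_kappa(cm)
    except ValueError:
        kappa = float("nan")
    return AgreementReport(
        accuracy=accuracy(cm),
        kappa=kappa,
        sensitivity=det["sensitivity"],
        specificity=det["specificity"],
        ppv=det["ppv"],
        npv=det["npv"],
        ba_mean_diff=mean_diff,
        ba_loa_low=lo,
        ba_loa_high=hi,
        pearson_r=r,
        ks_d=ks_d,
        ks_p=ks_p,
    ), cm
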