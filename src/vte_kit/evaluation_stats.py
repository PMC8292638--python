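"""Classifier evaluation metrics, ROC/AUC, chance deltas, and statistics.

Confusion-count metrics (accuracy, precision, recall, false-negative rate),
the ROC curve with trapezoidal AUC (equal to the Mann-Whitney concordance
probability with ties counted half), per-split delta scores against a
random-label baseline, and the statistical tests used throughout:
two-sample two-tailed KS, one-sample two-tailed Wilcoxon signed-rank,
Benjamini-Hochberg FDR correction, and pooled-SD Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spst
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "confusion_from_predictions",
    "classification_metrics",
    "roc_and_auc",
    "delta_scores",
    "ks_test_2samp",
    "wilcoxon_signed_rank",
    "bh_correct",
    "cohens_d",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def confusion_from_predictions(
    predicted: np.ndarray, truth: np.ndarray, positive: str = "VTE"
) -> ConfusionCounts:
    predicted = np.asarray(predicted, object)
    truth = np.asarray(truth, object)
    pp, tp_ = predicted == positive, truth == positive
    return ConfusionCounts(
        tp=int(np.sum(pp & tp_)),
        tn=int(np.sum(~pp & ~tp_)),
        fp=int(np.sum(pp & ~tp_)),
        fn=int(np.sum(~pp & tp_)),
    )


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, and FNR from confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); FNR = FN/(TP+FN). A metric with a zero
    denominator is reported as NaN (undefined), never as 0.
    """

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "precision": _ratio(c.tp, c.tp + c.fp),
        "recall": _ratio(c.tp, c.tp + c.fn),
        "fnr": _ratio(c.fn, c.tp + c.fn),
    }


def roc_and_auc(
    scores: np.ndarray, truth: np.ndarray, positive: str = "VTE"
) -> RocCurve:
    """ROC over all score thresholds with trapezoidal AUC.

    The abscissa is the conventional false positive rate. The trapezoidal
    area equals the probability that a random positive outranks a random
    negative, with tied scores counted half.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, object)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = (truth == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("need both classes for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    # trapezoidal area evaluated in integer count space so limit cases
    # (perfect separation, all ties) come out exact
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    tp = np.round(tpr * n_pos).astype(np.int64)
    fp = np.round(fpr * n_neg).astype(np.int64)
    area2 = np.sum((fp[1:] - fp[:-1]) * (tp[1:] + tp[:-1]))  # 2x area in counts
    auc = float(area2) / (2.0 * n_pos * n_neg)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def delta_scores(
    report: list[dict[str, float]],
    baseline: list[dict[str, float]],
) -> list[dict[str, float]]:
    """Per-split metric differences from the random-label baseline.

    Both runs must come from the same split matrix (matching ``split_id``
    per entry); a delta of zero means chance-level performance.
    """
    if len(report) != len(baseline):
        raise ValueError("reports must cover the same splits")
    out = []
    for r, b in zip(report, baseline):
        if r.get("split_id") != b.get("split_id"):
            raise ValueError("split_id mismatch between report and baseline")
        d = {"split_id": r.get("split_id")}
        for k in r:
            if k != "split_id" and k in b:
                d[f"delta_{k}"] = r[k] - b[k]
        out.append(d)
    return out


def ks_test_2samp(a: np.ndarray, b: np.ndarray, exact: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed Kolmogorov-Smirnov test: (D, p).

    Asymptotic p by default (samples here are large); exact available for
    small samples.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    res = spst.ks_2samp(a, b, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(diffs: np.ndarray) -> tuple[float, float]:
    """One-sample two-tailed Wilcoxon signed-rank test of symmetry about 0.

    Zero differences are dropped; ties are mid-ranked. Returns (W, p).
    All-zero input is degenerate and reported as (0, 1).
    """
    diffs = np.asarray(diffs, float)
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    if len(nz) < 6:
        raise ValueError("need at least 6 nonzero differences")
    res = spst.wilcoxon(nz, alternative="two-sided", zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def bh_correct(
    pvals: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejections."""
    pvals = np.asarray(pvals, float)
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return adjusted, rejected


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with pooled (n-1 weighted) SD.

    Returns NaN when the pooled SD is zero.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
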