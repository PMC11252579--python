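"""Evaluation surface: multiclass confusion matrix, one-vs-rest metrics,
ROC/PR curves with micro/macro AUC, and the repeated paired-split t-test for
comparing two classifiers.

Per-class counts derive from the C×C confusion matrix (rows = true class,
columns = predicted) by one-vs-rest decomposition:  TP_c = M[c,c],
FP_c = column sum − TP_c, FN_c = row sum − TP_c, TN_c = rest.  Metrics follow
Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R),
Accuracy = (TP+TN)/total, FPR = FP/(FP+TN), Specificity = 1 − FPR.  (Some
published tables print "FPR" for the quantity 1 − FP/(TN+FP), which is the
specificity; both quantities are reported here explicitly.)  Macro metrics
are unweighted means over classes; micro metrics pool TP/FP/FN first, which
for single-label multiclass data makes micro-F1 equal the plain accuracy.

The classifier comparison is the Dietterich-style repeated paired t-test:
each of r repetitions makes one random split, evaluates both classifiers
with the two roles swapped (score differences p_i⁽¹⁾, p_i⁽²⁾), pools the
per-repetition variances s_i² around their mean, and computes

    t = p_1⁽¹⁾ / sqrt(Σ_i s_i² / r),   df = r.

With r = 5 the two-sided critical value at α = 0.05 is 2.571.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .features import EncodedBatch

__all__ = ["ConfusionMatrix", "MetricReport", "TTestResult", "confusion",
           "metrics", "roc_pr_curves", "cv_paired_ttest",
           "ttest_critical_value", "slice_dataset"]


@dataclass(frozen=True)
class ConfusionMatrix:
    matrix: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def per_class_counts(self) -> dict[str, np.ndarray]:
        m = self.matrix
        tp = np.diag(m).astype(np.int64)
        fp = m.sum(axis=0) - tp
        fn = m.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Count matrix M[i, j] = #{true = i and predicted = j}."""
    y_true = np.asarray(y_true, np.int64)
    y_pred = np.asarray(y_pred, np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), np.int64)
    np.add.at(m, (y_true, y_pred), 1)
    return ConfusionMatrix(m)


def _safe_div(num, den):
    num = np.asarray(num, np.float64)
    den = np.asarray(den, np.float64)
    flagged = den == 0
    out = np.divide(num, den, out=np.zeros_like(num, np.float64),
                    where=~flagged)
    return out, flagged


@dataclass(frozen=True)
class MetricReport:
    """Per-class, macro and micro metrics with zero-division flags."""

    per_class: dict[str, np.ndarray]
    macro: dict[str, float]
    micro: dict[str, float]
    accuracy: float
    zero_division_flags: dict[str, np.ndarray]


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Compute the full metric report from a confusion matrix.

    Any metric with a zero denominator is reported as 0 and flagged.
    """
    counts = cm.per_class_counts()
    tp, fp, fn, tn = (counts[k] for k in ("tp", "fp", "fn", "tn"))
    precision, f_p = _safe_div(tp, tp + fp)
    recall, f_r = _safe_div(tp, tp + fn)
    f1, f_f = _safe_div(2 * precision * recall, precision + recall)
    acc_c, _ = _safe_div(tp + tn, tp + tn + fp + fn)
    fpr, f_fpr = _safe_div(fp, fp + tn)
    specificity = 1.0 - fpr
    per_class = {"precision": precision, "recall": recall, "f1": f1,
                 "accuracy": acc_c, "fpr": fpr, "specificity": specificity}
    macro = {k: float(v.mean()) for k, v in per_class.items()}
    tp_s, fp_s, fn_s, tn_s = tp.sum(), fp.sum(), fn.sum(), tn.sum()
    mp, _ = _safe_div(tp_s, tp_s + fp_s)
    mr, _ = _safe_div(tp_s, tp_s + fn_s)
    if mp == mr:
        # single-label multiclass pools to FP = FN, where the harmonic mean
        # reduces to the value itself; taking it directly keeps the
        # micro-F1 == accuracy identity exact in floating point
        mf1 = mp
    else:
        mf1, _ = _safe_div(2 * mp * mr, mp + mr)
    mfpr, _ = _safe_div(fp_s, fp_s + tn_s)
    micro = {"precision": float(mp), "recall": float(mr), "f1": float(mf1),
             "fpr": float(mfpr), "specificity": float(1.0 - mfpr)}
    accuracy = float(np.diag(cm.matrix).sum() / cm.total) if cm.total else 0.0
    return MetricReport(per_class=per_class, macro=macro, micro=micro,
                        accuracy=accuracy,
                        zero_division_flags={"precision": f_p, "recall": f_r,
                                             "f1": f_f, "fpr": f_fpr})


def roc_pr_curves(y_true_onehot, scores):
    """Threshold-swept ROC and PR curves with per-class, micro and macro AUC.

    A class absent from ``y_true`` has undefined AUC: it is reported as NaN
    and excluded from the macro average (flagged in ``absent_classes``).
    """
    y = np.asarray(y_true_onehot, np.float64)
    s = np.asarray(scores, np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_classes = y.shape[1]
    out = {"roc": {}, "pr": {}, "roc_auc": {}, "pr_auc": {},
           "absent_classes": []}
    aucs = []
    for c in range(n_classes):
        if y[:, c].sum() == 0 or y[:, c].sum() == len(y):
            out["roc_auc"][c] = float("nan")
            out["pr_auc"][c] = float("nan")
            out["absent_classes"].append(c)
            continue
        fpr, tpr, roc_thr = roc_curve(y[:, c], s[:, c])
        prec, rec, pr_thr = precision_recall_curve(y[:, c], s[:, c])
        out["roc"][c] = (fpr, tpr, roc_thr)
        out["pr"][c] = (rec, prec, pr_thr)
        out["roc_auc"][c] = float(_trapezoid_auc(fpr, tpr))
        out["pr_auc"][c] = float(_trapezoid_auc(rec, prec))
        aucs.append(out["roc_auc"][c])
    fpr_mi, tpr_mi, thr_mi = roc_curve(y.ravel(), s.ravel())
    out["roc"]["micro"] = (fpr_mi, tpr_mi, thr_mi)
    out["roc_auc"]["micro"] = float(_trapezoid_auc(fpr_mi, tpr_mi))
    prec_mi, rec_mi, prt_mi = precision_recall_curve(y.ravel(), s.ravel())
    out["pr"]["micro"] = (rec_mi, prec_mi, prt_mi)
    out["pr_auc"]["micro"] = float(_trapezoid_auc(rec_mi, prec_mi))
    out["roc_auc"]["macro"] = float(np.mean(aucs)) if aucs else float("nan")
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    threshold: float
    reject: bool
    pairs: tuple[tuple[float, float], ...]
    zero_variance: bool = False


def ttest_critical_value(df: int, alpha: float = 0.05) -> float:
    """Two-sided Student-t critical value (e.g. 2.571 at df=5, α=0.05)."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def slice_dataset(X, idx):
    """Row-subset an :class:`EncodedBatch` or array-like along axis 0."""
    if isinstance(X, EncodedBatch):
        return EncodedBatch(ids=X.ids[idx], mask=X.mask[idx],
                            labels=None if X.labels is None else X.labels[idx],
                            pad_id=X.pad_id)
    return np.asarray(X)[idx]



def cv_paired_ttest(builder_a, builder_b, X, y, repetitions: int = 5,
                    train_frac: float = 0.5, alpha: float = 0.05,
                    seed: int = 0) -> TTestResult:
    """Repeated paired-split t-test comparing two classifier builders.

    ``builder_a``/``builder_b`` are callables ``builder(seed) -> estimator``
    returning an unfitted model with deterministic seeded training.  Each
    repetition splits the data once, trains and scores both models, swaps the
    roles of the two parts and repeats, producing the accuracy-difference
    pair (p⁽¹⁾, p⁽²⁾) whose variance is pooled into the t statistic.
    """
    y = np.asarray(y)
    n = len(y)
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    p1_list, pairs, s2 = [], [], []
    for rep in range(repetitions):
        perm = rng.permutation(n)
        cut = max(1, int(round(train_frac * n)))
        part1, part2 = perm[:cut], perm[cut:]
        diffs = []
        for train_idx, test_idx in ((part1, part2), (part2, part1)):
            fit_seed = int(rng.integers(0, 2 ** 31))
            accs = []
            for builder in (builder_a, builder_b):
                model = builder(fit_seed)
                model.fit(slice_dataset(X, train_idx), y[train_idx])
                pred = model.predict(slice_dataset(X, test_idx))
                accs.append(float(np.mean(pred == y[test_idx])))
            diffs.append(accs[0] - accs[1])
        p1, p2 = diffs
        mean = (p1 + p2) / 2.0
        s2.append((p1 - mean) ** 2 + (p2 - mean) ** 2)
        p1_list.append(p1)
        pairs.append((p1, p2))
    pooled = float(np.sum(s2) / repetitions)
    zero_variance = pooled == 0.0
    t = 0.0 if zero_variance else float(p1_list[0] / np.sqrt(pooled))
    df = repetitions
    threshold = ttest_critical_value(df, alpha)
    p_value = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p_value=p_value, threshold=threshold,
                       reject=bool(abs(t) > threshold), pairs=tuple(pairs),
                       zero_variance=zero_variance)
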