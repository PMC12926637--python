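"""Evaluation metrics for binary DDI and multi-class event prediction.

Binary: accuracy, precision, recall, F1 (threshold 0.5 upstream), AUROC
via the Mann-Whitney rank statistic (probability that a random positive
outscores a random negative, ties counted 1/2) and AUPR via step
integration of the precision-recall curve.  Event mode adds macro-averaged
one-vs-rest precision/recall/F1 and macro AUROC/AUPR over classes present
in the labels, plus the confusion matrix.

Zero-denominator convention: precision and recall are reported as 0 with a
warning (never NaN), which keeps macro averages defined for rare classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class EvalReport:
    mode: str
    accuracy: float
    auroc: float
    aupr: float
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    macro_p: float | None = None
    macro_r: float | None = None
    macro_f1: float | None = None
    confusion: np.ndarray | None = None
    class_names: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"mode": self.mode, "accuracy": self.accuracy,
               "auroc": self.auroc, "aupr": self.aupr}
        for k in ("precision", "recall", "f1", "macro_p", "macro_r", "macro_f1"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def _zero_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting 0")
        return 0.0
    return num / den


def binary_metrics(labels, predictions):
    """(accuracy, precision, recall, f1) from hard 0/1 predictions."""
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(predictions, dtype=np.int64)
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} labels, {len(p)} predictions")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    accuracy = (tp + tn) / len(y)
    precision = _zero_div(tp, tp + fp, "precision")
    recall = _zero_div(tp, tp + fn, "recall")
    f1 = _zero_div(2 * precision * recall, precision + recall, "F1")
    return accuracy, precision, recall, f1


def rank_metrics(labels, scores):
    """(auroc, aupr) from continuous scores.

    AUROC is the Mann-Whitney statistic with tied scores counted half;
    AUPR integrates the precision-recall step curve (equivalently, average
    precision over the positives in score order).
    """
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if len(y) != len(s):
        raise ValueError(f"length mismatch: {len(y)} labels, {len(s)} scores")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rank metrics need both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    auroc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # step integration over distinct score thresholds (ties grouped):
    # AP = sum_i (R_i - R_{i-1}) P_i with P, R evaluated per threshold
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp_cum = np.cumsum(y_sorted)
    k = np.arange(1, len(y) + 1)
    last_of_group = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp_g = tp_cum[last_of_group]
    k_g = k[last_of_group]
    precision_g = tp_g / k_g
    recall_g = tp_g / n_pos
    delta_r = np.diff(np.r_[0.0, recall_g])
    aupr = float((precision_g * delta_r).sum())
    return float(auroc), aupr


def macro_metrics(labels, predictions):
    """Unweighted one-vs-rest (macro_p, macro_r, macro_f1) over classes
    present in the labels."""
    y = list(labels)
    p = list(predictions)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} labels, {len(p)} predictions")
    classes = sorted(set(y), key=lambda c: y.index(c))
    ps, rs, fs = [], [], []
    for c in classes:
        tp = sum(1 for a, b in zip(y, p) if a == c and b == c)
        fp = sum(1 for a, b in zip(y, p) if a != c and b == c)
        fn = sum(1 for a, b in zip(y, p) if a == c and b != c)
        prec = _zero_div(tp, tp + fp, f"precision[{c}]")
        rec = _zero_div(tp, tp + fn, f"recall[{c}]")
        ps.append(prec)
        rs.append(rec)
        fs.append(_zero_div(2 * prec * rec, prec + rec, f"F1[{c}]"))
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def confusion_matrix(labels, predictions, class_names):
    idx = {c: i for i, c in enumerate(class_names)}
    cm = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for a, b in zip(labels, predictions):
        cm[idx[a], idx[b]] += 1
    return cm


def evaluate_binary(labels, scores, threshold: float = 0.5) -> EvalReport:
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    acc, prec, rec, f1 = binary_metrics(y, (s >= threshold).astype(int))
    auroc, aupr = rank_metrics(y, s)
    return EvalReport("binary", acc, auroc, aupr,
                      precision=prec, recall=rec, f1=f1)


def evaluate_event(labels, prob_matrix, class_names) -> EvalReport:
    """Macro-averaged event-mode report from class-probability rows."""
    probs = np.asarray(prob_matrix, dtype=np.float64)
    y = list(labels)
    pred = [class_names[i] for i in probs.argmax(axis=1)]
    acc = float(np.mean([a == b for a, b in zip(y, pred)]))
    mp, mr, mf = macro_metrics(y, pred)
    present = [c for c in class_names if c in set(y)]
    aurocs, auprs = [], []
    for c in present:
        yc = np.array([1 if a == c else 0 for a in y])
        if yc.all() or not yc.any():
            continue
        a, p = rank_metrics(yc, probs[:, class_names.index(c)])
        aurocs.append(a)
        auprs.append(p)
    cm = confusion_matrix(y, pred, class_names)
    return EvalReport(
        "event", acc,
        float(np.mean(aurocs)) if aurocs else float("nan"),
        float(np.mean(auprs)) if auprs else float("nan"),
        macro_p=mp, macro_r=mr, macro_f1=mf,
        confusion=cm, class_names=list(class_names),
    )
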