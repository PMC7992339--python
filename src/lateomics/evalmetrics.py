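"""Classification, ranking and regression performance metrics.

Covers the binary-classification suite (accuracy, sensitivity, specificity,
precision, false positive rate, F1, Matthews correlation coefficient,
Cohen's kappa), rank-based AUROC, and regression summaries (MSE, Pearson r,
r^2).  Counts may be nonnegative reals: scale-normalized confusion matrices
(tp + fn = 1) yield identical ratio metrics.

Note on "false positive rate": it is computed here as fp / (fp + tn).
Published tables sometimes print 1 - precision (the false *discovery* rate)
under that name, so :func:`classification_metrics` also emits ``fdr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, rankdata


@dataclass
class ConfusionMatrix:
    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")
        if self.tp + self.fn + self.fp + self.tn <= 0:
            raise ValueError("confusion matrix is empty")

    @classmethod
    def from_labels(cls, y_true, y_pred, positive=1) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        t = y_true == positive
        p = y_pred == positive
        return cls(
            tp=float(np.sum(t & p)),
            fn=float(np.sum(t & ~p)),
            fp=float(np.sum(~t & p)),
            tn=float(np.sum(~t & ~p)),
        )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Standard binary metrics from a confusion matrix.

    Zero denominators yield a defined 0 with a warning.
    """
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    total = tp + fn + fp + tn
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    prec = _ratio(tp, tp + fp, "precision")
    fpr = _ratio(fp, fp + tn, "false_positive_rate")
    f1 = _ratio(2 * prec * sens, prec + sens, "f1")
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, float(mcc_den), "mcc")
    p_o = (tp + tn) / total
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / total**2
    kappa = _ratio(p_o - p_e, 1 - p_e, "kappa")
    return {
        "accuracy": p_o,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "false_positive_rate": fpr,
        "fdr": _ratio(fp, tp + fp, "fdr"),
        "f1": f1,
        "mcc": mcc,
        "kappa": kappa,
    }


def auroc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve; ties get midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def regression_metrics(y_true, y_pred) -> dict[str, float]:
    """MSE, Pearson r and r^2 over pairwise-complete observations."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ok = np.isfinite(y_true) & np.isfinite(y_pred)
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete pairs")
    yt, yp = y_true[ok], y_pred[ok]
    mse = float(np.mean((yt - yp) ** 2))
    if np.std(yt) == 0 or np.std(yp) == 0:
        warnings.warn("zero variance; Pearson r undefined", stacklevel=2)
        r = float("nan")
    else:
        r = float(pearsonr(yt, yp).statistic)
    return {"mse": mse, "pearson_r": r, "r_squared": r**2}
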