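"""Evaluation of chromatin features as enhancer-activity predictors.

Binary enhancer labels (e.g. a curated in-vivo enhancer catalog) are
predicted from continuous chromatin features (single-TF signal, number of
co-bound TFs, H3K27ac, accessibility); performance is summarized by
recall/precision at a fixed threshold and threshold-swept ROC curves with
AUC. The downstream ensemble classifier itself is out of scope: the module
exports a normalized feature matrix any learner can consume.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "recall_precision",
    "roc_auc",
    "minmax_normalize",
    "export_feature_table",
]


def recall_precision(
    labels: Sequence[int] | np.ndarray,
    predictions: Sequence[int] | np.ndarray,
) -> tuple[float, float, dict[str, int]]:
    """Recall and precision of binary predictions against binary labels.

    Returns (recall, precision, counts) where counts holds TP/FP/FN/TN.
    Precision is NaN when nothing is predicted positive.
    """
    y = np.asarray(labels, dtype=bool)
    yhat = np.asarray(predictions, dtype=bool)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must align")
    tp = int(np.sum(y & yhat))
    fp = int(np.sum(~y & yhat))
    fn = int(np.sum(y & ~yhat))
    tn = int(np.sum(~y & ~yhat))
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return recall, precision, {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def roc_auc(
    labels: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
) -> tuple[pd.DataFrame, float]:
    """Threshold-swept ROC curve and its trapezoidal AUC.

    Sweeps every unique score as a detection threshold. The AUC equals the
    midrank Mann–Whitney statistic, so tied scores are handled by rank
    averaging. Returns (curve, auc) with curve columns fpr, tpr, threshold.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("need both positive and negative labels")
    fpr, tpr, thr = _roc_curve(y, s)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(_auc(fpr, tpr))


def minmax_normalize(features: pd.DataFrame) -> pd.DataFrame:
    """Per-column min–max normalization to [0, 1].

    A constant column carries no information; it maps to all zeros with a
    warning rather than dividing by zero.
    """
    out = features.copy().astype(float)
    for col in out.columns:
        x = out[col].to_numpy()
        lo, hi = np.min(x), np.max(x)
        if hi == lo:
            warnings.warn(
                f"feature {col!r} is constant; normalized to 0",
                stacklevel=2,
            )
            out[col] = 0.0
        else:
            out[col] = (x - lo) / (hi - lo)
    return out


def export_feature_table(
    features: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    path: str,
    normalize: bool = True,
) -> pd.DataFrame:
    """Write the (optionally normalized) feature matrix + labels as TSV.

    The exported table is the hand-off point to any external classifier;
    columns are the feature names plus a final ``label`` column.
    """
    mat = minmax_normalize(features) if normalize else features.copy()
    mat = mat.copy()
    mat["label"] = np.asarray(labels, dtype=int)
    mat.to_csv(path, sep="\t", index=False)
    return mat
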