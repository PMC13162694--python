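"""Classification metrics.

ROC-AUC is computed as the Mann–Whitney rank statistic with midranks for
ties; F1 and accuracy threshold the positive-class probability at 0.5 by
default (the positive class is the progressor/minority class).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError

__all__ = ["roc_auc", "f1_score", "accuracy", "metrics"]


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("ROC-AUC undefined for single-class labels")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def f1_score(probabilities: np.ndarray, labels: np.ndarray, threshold=0.5) -> float:
    y = np.asarray(labels, dtype=int)
    pred = (np.asarray(probabilities, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)


def accuracy(probabilities: np.ndarray, labels: np.ndarray, threshold=0.5) -> float:
    y = np.asarray(labels, dtype=int)
    pred = (np.asarray(probabilities, dtype=float) >= threshold).astype(int)
    return float(np.mean(pred == y))


def metrics(probabilities, labels, threshold: float = 0.5) -> dict[str, float]:
    """(ROC-AUC, F1, accuracy) for one fold's test predictions."""
    return {
        "auc": roc_auc(probabilities, labels),
        "f1": f1_score(probabilities, labels, threshold),
        "accuracy": accuracy(probabilities, labels, threshold),
    }
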