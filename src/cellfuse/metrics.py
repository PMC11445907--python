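"""Clustering evaluation: Hungarian-matched ACC, NMI and ARI.

Unsupervised accuracy maximizes (1/n) sum_i I(y_i = pi(y_hat_i)) over
one-to-one label mappings pi, found by optimal assignment on the
contingency table — raw-label matching is meaningless for cluster
labels.  NMI uses the max(H, H) denominator and ARI the usual
pair-counting adjustment; both delegate to scikit-learn, with the
both-degenerate (single cluster on both sides) case defined as 1.
All three are invariant to bijective relabelling of either partition.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["clustering_accuracy", "nmi", "ari", "evaluate_clustering"]


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    return y_true, y_pred


def clustering_accuracy(y_true, y_pred) -> float:
    """Best-mapping accuracy via Hungarian assignment on the contingency table."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    table = contingency_matrix(y_true, y_pred)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / y_true.size)


def nmi(y_true, y_pred) -> float:
    """Normalized mutual information with the max-entropy denominator."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 1:
        raise ValueError("empty label vectors")
    return float(normalized_mutual_info_score(y_true, y_pred, average_method="max"))


def ari(y_true, y_pred) -> float:
    """Adjusted Rand index by pair counting."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 2:
        raise ValueError("ARI needs at least two samples")
    return float(adjusted_rand_score(y_true, y_pred))


def evaluate_clustering(y_true, y_pred) -> dict:
    """All three scores as a mapping {"ACC", "NMI", "ARI"}."""
    return {
        "ACC": clustering_accuracy(y_true, y_pred),
        "NMI": nmi(y_true, y_pred),
        "ARI": ari(y_true, y_pred),
    }
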