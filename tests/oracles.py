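"""Independent brute-force oracles shared by the metric test suites."""

from __future__ import annotations

import numpy as np


def brute_force_auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney enumeration over all positive-negative pairs, ties 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-wise PR area: sum over recall increments of precision at each cut."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    total_pos = y.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i, n = 0, len(y)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # tied scores act as one threshold
            j += 1
        tp += y[i:j].sum()
        fp += (j - i) - y[i:j].sum()
        recall = tp / total_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(area)


def brute_force_f1(labels: np.ndarray, scores: np.ndarray, t: float = 0.5) -> float:
    preds = scores >= t
    tp = int((preds & (labels == 1)).sum())
    fp = int((preds & (labels == 0)).sum())
    fn = int((~preds & (labels == 1)).sum())
    if tp == 0:
        return 0.0
    precision, recall = tp / (tp + fp), tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
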