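"""Classifier performance metrics: AUROC, AUPR, F1, per cell type and pooled.

AUROC equals the Mann-Whitney probability that a random positive outscores a
random negative (ties counted 1/2). AUPR is the area under the step-wise
precision-recall curve. F1 is evaluated at a fixed probability threshold
(default 0.5, the sigmoid midpoint); when nothing is predicted positive it is
0 by convention. The pooled ("micro") aggregate flattens all
(example, cell type) pairs into one binary problem; a macro average over
cell types is available as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .model import ClassifierModel, predict
from .seqdata import EncodedExample


def auroc(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValueError("AUROC undefined: need at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def aupr(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray) -> float:
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined: need at least one positive")
    return float(average_precision_score(labels, np.asarray(scores)))


def f1(labels: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray,
       threshold: float = 0.5) -> float:
    labels = np.asarray(labels)
    preds = (np.asarray(scores) >= threshold).astype(int)
    return float(f1_score(labels, preds, zero_division=0))


@dataclass
class MetricReport:
    """Per-cell-type and aggregate test-set metrics."""

    per_cell_type: list[dict]
    micro_auroc: float
    micro_aupr: float
    micro_f1: float
    macro_auroc: float
    macro_aupr: float
    macro_f1: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = list(self.per_cell_type)
        rows.append(
            {"cell_type": "micro", "auroc": self.micro_auroc, "aupr": self.micro_aupr,
             "f1": self.micro_f1, "n_pos": sum(r["n_pos"] for r in self.per_cell_type),
             "n_neg": sum(r["n_neg"] for r in self.per_cell_type)}
        )
        rows.append(
            {"cell_type": "macro", "auroc": self.macro_auroc, "aupr": self.macro_aupr,
             "f1": self.macro_f1, "n_pos": np.nan, "n_neg": np.nan}
        )
        return pd.DataFrame(rows)


def metric_report(
    labels: np.ndarray, scores: np.ndarray, cell_types: Sequence[str] | None = None
) -> MetricReport:
    """Compute the report from an (n, m) label matrix and matching scores.

    Cell types whose test labels are single-class get NA metrics and are
    excluded from the macro average; the micro aggregate always pools every
    (example, cell type) pair.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.size == 0:
        raise ValueError("empty test set")
    m = labels.shape[1]
    names = list(cell_types) if cell_types is not None else [f"ct{c}" for c in range(m)]
    rows = []
    for c in range(m):
        y, s = labels[:, c], scores[:, c]
        n_pos, n_neg = int(y.sum()), int(y.size - y.sum())
        if n_pos == 0 or n_neg == 0:
            rows.append({"cell_type": names[c], "auroc": np.nan, "aupr": np.nan,
                         "f1": np.nan, "n_pos": n_pos, "n_neg": n_neg})
        else:
            rows.append({"cell_type": names[c], "auroc": auroc(y, s), "aupr": aupr(y, s),
                         "f1": f1(y, s), "n_pos": n_pos, "n_neg": n_neg})
    flat_y, flat_s = labels.ravel(), scores.ravel()
    valid = [r for r in rows if not np.isnan(r["auroc"])]
    return MetricReport(
        per_cell_type=rows,
        micro_auroc=auroc(flat_y, flat_s),
        micro_aupr=aupr(flat_y, flat_s),
        micro_f1=f1(flat_y, flat_s),
        macro_auroc=float(np.mean([r["auroc"] for r in valid])) if valid else np.nan,
        macro_aupr=float(np.mean([r["aupr"] for r in valid])) if valid else np.nan,
        macro_f1=float(np.mean([r["f1"] for r in valid])) if valid else np.nan,
    )


def evaluate_model(
    model: ClassifierModel,
    test_set: Sequence[EncodedExample],
    cell_types: Sequence[str] | None = None,
) -> MetricReport:
    """Score the test set with strand-max prediction and compute the report."""
    if not test_set:
        raise ValueError("empty test set")
    labels = np.stack([ex.labels for ex in test_set])
    scores = predict(model, test_set)
    return metric_report(labels, scores, cell_types)
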