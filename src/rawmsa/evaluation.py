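"""Evaluation metrics: Qn per-residue accuracy and CASP-style top-L/5
long-range contact precision.

Dataset-level numbers are unweighted means over targets (every protein
counts equally, regardless of length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import LONG_RANGE_MIN_SEPARATION, ContactMap

__all__ = [
    "multiclass_accuracy",
    "top_l5_long_range_precision",
    "random_long_range_baseline",
    "evaluate_dataset",
    "EvaluationReport",
]


def multiclass_accuracy(pred, truth, mask=None) -> float:
    """Correct / total over unmasked positions (Q3, Q4, Q2 ...)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if mask is None:
        mask = np.ones(pred.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("all positions are masked")
    return float((pred[mask] == truth[mask]).sum() / n)


def _eligible_pairs(length: int, mask: np.ndarray) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i in range(length)
        for j in range(i + LONG_RANGE_MIN_SEPARATION, length)
        if mask[i] and mask[j]
    ]


def top_l5_long_range_precision(pred: np.ndarray, truth) -> float:
    """Precision of the floor(L/5) highest-scored long-range pairs.

    Pairs are upper-triangle (i < j) with separation over 23, excluding any
    masked residue; ranking is by predicted probability descending with
    ties broken by ascending (i, j). At least one pair is always selected
    when any is eligible; if fewer eligible pairs exist than floor(L/5),
    precision is over those actually selected. The metric depends only on
    the ranking, so any monotone transform of the scores leaves it
    unchanged.
    """
    truth_map = truth if isinstance(truth, ContactMap) else ContactMap(np.asarray(truth))
    pred = np.asarray(pred)
    if pred.shape != truth_map.values.shape:
        raise ValueError("prediction and truth maps have different shapes")
    length = truth_map.length
    pairs = _eligible_pairs(length, truth_map.mask)
    if not pairs:
        return 0.0
    pairs.sort(key=lambda p: (-pred[p], p))
    n_select = min(max(length // 5, 1), len(pairs))
    selected = pairs[:n_select]
    hits = sum(int(truth_map.values[p]) for p in selected)
    return hits / n_select


def random_long_range_baseline(truth) -> float:
    """Expected top-L/5 precision of a uniformly random ranking: the
    long-range contact density."""
    truth_map = truth if isinstance(truth, ContactMap) else ContactMap(np.asarray(truth))
    pairs = _eligible_pairs(truth_map.length, truth_map.mask)
    if not pairs:
        return 0.0
    return sum(int(truth_map.values[p]) for p in pairs) / len(pairs)


@dataclass
class EvaluationReport:
    """Per-target metric table plus the unweighted dataset mean."""

    per_target: pd.DataFrame
    mean: float

    def __repr__(self):
        return f"EvaluationReport(n_targets={len(self.per_target)}, mean={self.mean:.4f})"


def evaluate_dataset(predictions: dict, truths: dict, metric) -> EvaluationReport:
    """Apply ``metric(pred, truth)`` per target and average with equal
    weight per target. Every truth target must have a prediction."""
    missing = sorted(set(truths) - set(predictions))
    if missing:
        raise ValueError(f"missing predictions for targets: {missing}")
    rows = []
    for target in sorted(truths):
        rows.append({"target": target, "value": metric(predictions[target], truths[target])})
    table = pd.DataFrame(rows).set_index("target")
    return EvaluationReport(per_target=table, mean=float(table["value"].mean()))
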