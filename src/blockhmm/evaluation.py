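"""Benchmark metrics: sensitivity, specificity and MCC with collapsed states.

Negative and Positive Influence are collapsed into a single "influential"
class before scoring, so a sign confusion still counts as a true positive.
Trials whose truth contains no influential site report sensitivity and MCC as
NA, and NA entries are excluded from aggregate means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputValidationError


@dataclass
class ConfusionSummary:
    """Binary confusion counts and derived metrics after collapsing +-1.

    Metrics that are undefined for the trial (no true positives in truth for
    sensitivity/MCC, no true negatives for specificity) are ``nan``.
    ``matrix3x3`` is the uncollapsed state-by-state confusion table
    (rows: truth -1/0/+1, columns: calls) kept for diagnostics.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float
    specificity: float
    mcc: float
    matrix3x3: np.ndarray | None = None


def _collapse(vec: np.ndarray, name: str) -> np.ndarray:
    vec = np.asarray(vec)
    if not np.all(np.isin(vec, (-1, 0, 1))):
        raise InputValidationError(f"{name} must contain only -1, 0 or 1")
    return (vec != 0).astype(np.int64)


def confusion_metrics(truth: np.ndarray, calls: np.ndarray) -> ConfusionSummary:
    """Score a call vector against ground-truth states.

    ``truth`` has entries in {-1, 0, +1}; ``calls`` may be ternary (HMM
    output) or already binary (baseline output).  Both are collapsed to
    influential / not-influential.  MCC uses its standard formula; when truth
    has positives but a denominator factor is zero, MCC is 0 by convention.
    """
    truth = np.asarray(truth)
    calls = np.asarray(calls)
    if truth.shape != calls.shape:
        raise InputValidationError(
            f"truth has length {truth.size} but calls has length {calls.size}"
        )
    t = _collapse(truth, "truth")
    c = _collapse(calls, "calls")

    tp = int(np.sum((t == 1) & (c == 1)))
    fn = int(np.sum((t == 1) & (c == 0)))
    tn = int(np.sum((t == 0) & (c == 0)))
    fp = int(np.sum((t == 0) & (c == 1)))

    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    specificity = tn / (tn + fp) if (tn + fp) > 0 else math.nan

    if (tp + fn) == 0:
        mcc = math.nan
    else:
        denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0

    matrix = np.zeros((3, 3), dtype=np.int64)
    for i, s_true in enumerate((-1, 0, 1)):
        for j, s_call in enumerate((-1, 0, 1)):
            matrix[i, j] = int(np.sum((truth == s_true) & (calls == s_call)))

    return ConfusionSummary(tp, fp, tn, fn, sensitivity, specificity, mcc, matrix)


def aggregate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method means (NA-excluded) and the sample SD of MCC.

    ``table`` needs columns ``method``, ``trial``, ``sensitivity``,
    ``specificity`` and ``mcc``.  NA entries reduce the divisor rather than
    being treated as zero; a method whose MCCs are all NA aggregates to NA.
    """
    if table is None or len(table) == 0:
        raise InputValidationError("empty trial table")
    required = {"method", "sensitivity", "specificity", "mcc"}
    missing = required - set(table.columns)
    if missing:
        raise InputValidationError(f"trial table missing columns: {sorted(missing)}")
    grouped = table.groupby("method", sort=False)
    out = grouped.agg(
        sensitivity=("sensitivity", "mean"),
        specificity=("specificity", "mean"),
        mcc=("mcc", "mean"),
        mcc_sd=("mcc", lambda s: s.std(ddof=1)),
        n_trials=("mcc", "size"),
    )
    return out.reset_index()
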