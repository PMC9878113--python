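"""Differential-expression calling on log2 expression matrices.

For each feature an unpaired two-tailed t-test (Welch by default, pooled
available) compares two sample groups; p-values are Benjamini-Hochberg
adjusted across all tested features of the platform/comparison; fold
change is the geometric-mean ratio 2^(mean_a - mean_b); and a feature is
called Lower/Higher only under the dual threshold adjusted P < alpha and
fold change >= fc_threshold or <= 1/fc_threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SchemaError

LOWER = "Lower"
HIGHER = "Higher"
NOT_SIGNIFICANT = "NotSignificant"


@dataclass
class DifferentialRecord:
    feature_id: str
    mean_log2_a: float
    mean_log2_b: float
    log2fc: float  # a - b
    fold_change: float  # 2 ** log2fc
    p_raw: float
    p_adj: float
    direction: str


def welch_t_test(
    x: Sequence[float], y: Sequence[float], variance_mode: str = "welch"
) -> tuple[float, float]:
    """Unpaired two-tailed t-test; Welch-Satterthwaite or pooled df.

    Degenerate variance cases are resolved by the limit: equal means give
    (t=0, p=1), unequal means with zero spread give (t=+-inf, p=0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite observations")
    if variance_mode not in ("welch", "pooled"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn("zero variance in both groups with unequal means; p -> 0 limit")
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=(variance_mode == "pooled"))
    return float(t), float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; returns adjusted p-values in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    variance_mode: str = "welch",
) -> list[DifferentialRecord]:
    """Per-feature DE records for the contrast group_a vs group_b.

    The BH family is all features of the supplied (already
    detection-filtered) matrix; fold change is 2^(mean_a - mean_b) so
    values above 1 mean higher expression in group_a.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise SchemaError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise SchemaError("each group needs at least 2 samples")
    missing = [s for s in group_a + group_b if s not in matrix.values.columns]
    if missing:
        raise SchemaError(f"samples not in matrix: {missing}")
    if matrix.scale != "log2":
        raise SchemaError("differential expression expects a log2-scale matrix")

    a = matrix.values[group_a].to_numpy()
    b = matrix.values[group_b].to_numpy()
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(variance_mode == "pooled"))
    # zero-variance features: p is nan; resolve by the degenerate-case limit
    nan_mask = ~np.isfinite(p)
    if nan_mask.any():
        p = p.copy()
        p[nan_mask & (mean_a == mean_b)] = 1.0
        p[nan_mask & (mean_a != mean_b)] = 0.0
    p_adj = benjamini_hochberg(p)
    log2fc = mean_a - mean_b
    fc = np.exp2(log2fc)

    records = []
    for i, feature in enumerate(matrix.feature_ids):
        direction = NOT_SIGNIFICANT
        if p_adj[i] < alpha:
            if fc[i] >= fc_threshold:
                direction = HIGHER
            elif fc[i] <= 1.0 / fc_threshold:
                direction = LOWER
        records.append(
            DifferentialRecord(
                feature_id=feature,
                mean_log2_a=float(mean_a[i]),
                mean_log2_b=float(mean_b[i]),
                log2fc=float(log2fc[i]),
                fold_change=float(fc[i]),
                p_raw=float(p[i]),
                p_adj=float(p_adj[i]),
                direction=direction,
            )
        )
    return records


def records_to_frame(records: Sequence[DifferentialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_id, r.mean_log2_a, r.mean_log2_b, r.log2fc, r.fold_change, r.p_raw, r.p_adj, r.direction)
            for r in records
        ],
        columns=[
            "feature_id",
            "mean_log2_a",
            "mean_log2_b",
            "log2fc",
            "fold_change",
            "p_raw",
            "p_adj",
            "direction",
        ],
    )


def export_volcano(
    records: Sequence[DifferentialRecord], neg_log10_ceiling: float = 300.0
) -> pd.DataFrame:
    """Volcano-plot table: feature, log2fc, -log10(adjusted p), direction."""
    rows = []
    for r in records:
        if r.p_adj > 0:
            y = -np.log10(r.p_adj)
        else:
            y = neg_log10_ceiling
        rows.append((r.feature_id, r.log2fc, min(y, neg_log10_ceiling), r.direction))
    return pd.DataFrame(rows, columns=["feature_id", "log2fc", "neg_log10_p_adj", "direction"])


def count_passing(
    table: pd.DataFrame, alpha: float = 0.05, fc_high: float = 1.5, fc_low: float = 0.67
) -> int:
    """Count printed-table rows passing the dual screening threshold.

    Printed fold changes carry 2 decimals, so the lower bound is the
    rounded image 0.67 of the exact reciprocal 1/1.5.
    """
    passing = (table["adjusted_p"] < alpha) & (
        (table["fold_change"] >= fc_high) | (table["fold_change"] <= fc_low)
    )
    return int(passing.sum())
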