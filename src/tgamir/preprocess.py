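"""Array preprocessing: detection filtering, quantile normalization, log2,
and sample/feature dendrograms for QC heatmaps.

The chain mirrors standard two-color-era array practice: drop features
whose detection rate is too low, force every sample onto a common
intensity distribution, move to log2, and inspect average-linkage
Euclidean dendrograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix, SchemaError


@dataclass
class FilterReport:
    kept_features: list[str]
    dropped_features: list[str]
    detection_fractions: pd.DataFrame  # feature x group detection rates


@dataclass
class Dendrogram:
    """Agglomerative merge history: (node_a, node_b, height) per merge.

    Leaves are numbered 0..n-1 in ``labels`` order; internal nodes n, n+1,
    ... in merge order, as in scipy's linkage encoding.
    """

    merges: list[tuple[int, int, float]]
    labels: list[str]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def detection_filter(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    min_rate: float = 0.5,
    mode: str = "any_group",
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features with inadequate per-group detection rates.

    ``mode="any_group"`` keeps a feature if its detection rate reaches
    ``min_rate`` in at least one group; ``"all_groups"`` requires every
    group.  The default corresponds to the common reading of a "detected in
    at least 50% of one group" rule.
    """
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must lie in (0, 1]")
    if mode not in ("any_group", "all_groups"):
        raise ValueError(f"unknown mode {mode!r}")
    group_of = metadata.set_index("sample_id")["group"]
    missing = [s for s in matrix.sample_ids if s not in group_of.index]
    if missing:
        raise SchemaError(f"samples missing from annotation: {missing}")
    groups = group_of.loc[matrix.sample_ids]
    fractions = {}
    for g in pd.unique(groups):
        cols = [s for s in matrix.sample_ids if groups[s] == g]
        fractions[g] = matrix.detected[cols].mean(axis=1)
    frac = pd.DataFrame(fractions)
    if mode == "any_group":
        keep_mask = (frac >= min_rate).any(axis=1)
    else:
        keep_mask = (frac >= min_rate).all(axis=1)
    kept = list(frac.index[keep_mask])
    dropped = list(frac.index[~keep_mask])
    return matrix.subset_features(kept), FilterReport(kept, dropped, frac)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the vector of row-wise means of the per-sample sorted
    intensity columns; each cell is replaced by the reference value at its
    within-column rank.  Ties within a column receive the mean of the
    reference values across the tied span, so within-column rank order is
    preserved (ties stay tied).
    """
    if matrix.scale != "raw":
        raise SchemaError("quantile normalization expects a raw-scale matrix")
    values = matrix.values.to_numpy(dtype=float)
    n_features, n_samples = values.shape
    if n_features < 2:
        warnings.warn("quantile normalization of a single-feature matrix is a no-op")
        return ExpressionMatrix(
            matrix.values.copy(), matrix.detected.copy(), scale="raw", platform=matrix.platform
        )
    reference = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_features)
        assigned[order] = reference
        # average the reference over tied spans so tied inputs stay tied
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_features]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.detected.copy(),
        scale="raw",
        platform=matrix.platform,
    )


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset); the offset guards zeros on the raw scale."""
    if matrix.scale != "raw":
        raise SchemaError("log2_transform expects a raw-scale matrix")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    arr = matrix.values.to_numpy()
    if np.any(arr + offset <= 0):
        raise ValueError("log2 transform undefined: value + offset <= 0")
    return ExpressionMatrix(
        pd.DataFrame(
            np.log2(arr + offset), index=matrix.values.index, columns=matrix.values.columns
        ),
        matrix.detected.copy(),
        scale="log2",
        platform=matrix.platform,
    )


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "samples") -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram under Euclidean distance.

    Items are ordered lexicographically by id before clustering so that
    distance ties resolve deterministically regardless of input order.
    """
    if matrix.scale != "log2":
        raise SchemaError("clustering expects a log2-scale matrix")
    if axis == "samples":
        data = matrix.values.T
    elif axis == "features":
        data = matrix.values
    else:
        raise ValueError(f"unknown axis {axis!r}")
    labels = sorted(data.index)
    if len(labels) < 2:
        warnings.warn("clustering a single item yields a trivial tree")
        return Dendrogram(merges=[], labels=list(labels))
    points = data.loc[labels].to_numpy(dtype=float)
    z = linkage(pdist(points, metric="euclidean"), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(merges=merges, labels=labels)
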