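"""Inverse miRNA-mRNA correlation network.

Every pair of a differentially expressed miRNA and a differentially
expressed mRNA with *opposite* regulation directions and a predicted
binding site in the gene's 3'UTR is scored by Spearman correlation across
the chosen samples; a pair becomes a network edge only when the
correlation is negative and strong (rho <= -0.5 by default) with P < 0.05.
The rationale is mechanistic: a repressive miRNA should move opposite to
its target both across groups (DE directions) and across individuals
(negative rank correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .diffexpr import DifferentialRecord, HIGHER, LOWER, benjamini_hochberg
from .io import BindingSiteTable, CorrelationEdge, ExpressionMatrix, SchemaError


@dataclass
class NetworkSummary:
    n_edges: int
    n_mirna_lower: int
    n_mirna_higher: int
    n_mrna_lower: int
    n_mrna_higher: int
    n_edges_lower_mirna_higher_mrna: int
    n_edges_higher_mirna_lower_mrna: int


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    The two-sided p-value uses the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom; |rho| = 1
    returns p = 0 as the limit.  Constant input has no defined rank
    correlation and returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need two equal-length vectors with at least 4 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    if abs(rho) == 1.0:
        return float(rho), 0.0
    return float(rho), float(p)


def build_network(
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    de_mirna: Sequence[DifferentialRecord],
    de_mrna: Sequence[DifferentialRecord],
    sites: BindingSiteTable,
    samples: Sequence[str] | None = None,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
    require_negative: bool = True,
    adjust_p: bool = False,
) -> tuple[list[CorrelationEdge], NetworkSummary]:
    """Assemble the inverse-correlation network.

    Candidate pairs are DE-miRNA x DE-mRNA with opposite directions and a
    3'UTR binding site; each is scored by Spearman correlation over
    ``samples`` (default: all samples common to both matrices) and retained
    iff rho <= -rho_threshold (or |rho| >= rho_threshold with
    ``require_negative=False``) and p < alpha.  ``adjust_p`` applies BH
    across candidate pairs before the alpha gate (off by default: the gate
    is a raw per-pair P < 0.05).
    """
    if mirna_matrix.scale != "log2" or mrna_matrix.scale != "log2":
        raise SchemaError("network construction expects log2-scale matrices")
    if samples is None:
        samples = [s for s in mirna_matrix.sample_ids if s in set(mrna_matrix.sample_ids)]
    samples = list(samples)
    missing = [
        s
        for s in samples
        if s not in mirna_matrix.values.columns or s not in mrna_matrix.values.columns
    ]
    if missing:
        raise SchemaError(f"samples absent from a matrix: {missing}")

    mi_called = sorted(
        (r for r in de_mirna if r.direction in (LOWER, HIGHER)), key=lambda r: r.feature_id
    )
    m_called = sorted(
        (r for r in de_mrna if r.direction in (LOWER, HIGHER)), key=lambda r: r.feature_id
    )
    candidates = [
        (mi, m)
        for mi in mi_called
        for m in m_called
        if mi.direction != m.direction and sites.has_site(mi.feature_id, m.feature_id)
    ]
    stats_out = []
    for mi, m in candidates:
        x = mirna_matrix.values.loc[mi.feature_id, samples].to_numpy()
        y = mrna_matrix.values.loc[m.feature_id, samples].to_numpy()
        rho, p = spearman(x, y)
        stats_out.append((mi, m, rho, p))
    if adjust_p and stats_out:
        finite = [i for i, s in enumerate(stats_out) if np.isfinite(s[3])]
        adj = benjamini_hochberg([stats_out[i][3] for i in finite])
        for i, a_p in zip(finite, adj):
            mi, m, rho, _ = stats_out[i]
            stats_out[i] = (mi, m, rho, float(a_p))
    edges = []
    for mi, m, rho, p in stats_out:
        if not np.isfinite(rho) or not np.isfinite(p):
            continue
        magnitude_ok = rho <= -rho_threshold if require_negative else abs(rho) >= rho_threshold
        if magnitude_ok and p < alpha:
            edges.append(
                CorrelationEdge(
                    mirna_id=mi.feature_id,
                    mrna_id=m.feature_id,
                    rho=rho,
                    p=p,
                    mirna_direction=mi.direction,
                    mrna_direction=m.direction,
                    has_site=True,
                    n_samples=len(samples),
                )
            )
    return edges, summarize_network(edges)


def summarize_network(edges: Sequence[CorrelationEdge]) -> NetworkSummary:
    """Node and edge tallies by regulation-direction pattern.

    Node counts are over distinct features (an mRNA targeted by several
    miRNAs counts once), edge-pattern counts over pairs; the two pattern
    counts always sum to the edge count.
    """
    mirna_lower = {e.mirna_id for e in edges if e.mirna_direction == LOWER}
    mirna_higher = {e.mirna_id for e in edges if e.mirna_direction == HIGHER}
    mrna_lower = {e.mrna_id for e in edges if e.mrna_direction == LOWER}
    mrna_higher = {e.mrna_id for e in edges if e.mrna_direction == HIGHER}
    low_hi = sum(1 for e in edges if e.mirna_direction == LOWER and e.mrna_direction == HIGHER)
    hi_low = sum(1 for e in edges if e.mirna_direction == HIGHER and e.mrna_direction == LOWER)
    return NetworkSummary(
        n_edges=len(edges),
        n_mirna_lower=len(mirna_lower),
        n_mirna_higher=len(mirna_higher),
        n_mrna_lower=len(mrna_lower),
        n_mrna_higher=len(mrna_higher),
        n_edges_lower_mirna_higher_mrna=low_hi,
        n_edges_higher_mirna_lower_mrna=hi_low,
    )


def validate_edges(
    edges: Sequence[CorrelationEdge],
    sites: BindingSiteTable,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
) -> None:
    """Independent post-hoc re-check of the four edge gates."""
    for e in edges:
        if not sites.has_site(e.mirna_id, e.mrna_id):
            raise AssertionError(f"edge {e.mirna_id}-{e.mrna_id} lacks a binding site")
        if not e.rho <= -rho_threshold:
            raise AssertionError(f"edge {e.mirna_id}-{e.mrna_id} fails the rho gate")
        if not e.p < alpha:
            raise AssertionError(f"edge {e.mirna_id}-{e.mrna_id} fails the p gate")
        if e.mirna_direction == e.mrna_direction:
            raise AssertionError(f"edge {e.mirna_id}-{e.mrna_id} is not inverse-regulated")
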