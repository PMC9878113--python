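"""RT-qPCR relative quantification against an endogenous reference.

Ct values above the usability gate (default 35 cycles) are discarded per
sample/assay; the remaining assays are normalized to the reference small
RNA (RNU6B by default) as dCt = Ct_assay - Ct_reference, so lower dCt
means higher abundance.  Group comparison runs an unpaired two-tailed
t-test on dCt with BH adjustment across the assay panel, and fold change
is 2^(-ddCt) with ddCt the difference of group-mean dCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import (
    HIGHER,
    LOWER,
    DifferentialRecord,
    benjamini_hochberg,
    welch_t_test,
)
from .io import SchemaError

SIGNIFICANT_SAME = "significant_same_direction"
SAME_NS = "same_direction_ns"
INVERSE = "inverse"
NOT_EVALUABLE = "not_evaluable"


@dataclass
class DeltaCtResult:
    assay_id: str
    mean_dct_a: float
    mean_dct_b: float
    ddct: float  # mean_dct_a - mean_dct_b
    fold_change: float  # 2 ** (-ddct)
    p_raw: float
    p_adj: float
    n_a: int
    n_b: int
    concordance: str = NOT_EVALUABLE


def compute_delta_ct(
    ct_table: pd.DataFrame, reference_id: str = "RNU6B", gate: float = 35.0
) -> pd.DataFrame:
    """Per-sample dCt = Ct_assay - Ct_reference after Ct-gating.

    Samples whose reference assay is missing or fails the gate are dropped
    entirely; individual assay measurements failing the gate are dropped
    for that assay only.  Returns a long table (sample_id, assay_id, dct).
    """
    required = {"sample_id", "assay_id", "ct"}
    if not required <= set(ct_table.columns):
        raise SchemaError(f"Ct table needs columns {sorted(required)}")
    ref = ct_table[ct_table["assay_id"] == reference_id]
    if ref.empty:
        raise SchemaError(f"reference assay {reference_id!r} absent from Ct table")
    ref_ct = ref.set_index("sample_id")["ct"]
    usable_ref = ref_ct[ref_ct <= gate]
    lost = sorted(set(ref_ct.index) - set(usable_ref.index))
    if lost:
        warnings.warn(f"reference fails the Ct gate in samples {lost}; samples excluded")
    assays = ct_table[ct_table["assay_id"] != reference_id]
    assays = assays[assays["sample_id"].isin(usable_ref.index)]
    assays = assays[assays["ct"] <= gate]
    out = assays.copy()
    out["dct"] = out["ct"].to_numpy() - usable_ref.loc[out["sample_id"]].to_numpy()
    return out[["sample_id", "assay_id", "dct"]].reset_index(drop=True)


def compare_groups_dct(
    dct_table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
) -> list[DeltaCtResult]:
    """Unpaired two-tailed t-test on dCt per assay, BH across the panel.

    ddCt = mean dCt(group_a) - mean dCt(group_b); since lower dCt means
    higher abundance, relative expression of group_a vs group_b is
    2^(-ddCt).  Assays with fewer than two usable samples in either group
    are reported as not evaluable (p and fold change NaN).
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise SchemaError("groups overlap")
    results: list[DeltaCtResult] = []
    p_raw: list[float] = []
    testable: list[int] = []
    for idx, (assay, sub) in enumerate(sorted(dct_table.groupby("assay_id"))):
        a = sub[sub["sample_id"].isin(group_a)]["dct"].to_numpy()
        b = sub[sub["sample_id"].isin(group_b)]["dct"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            results.append(
                DeltaCtResult(assay, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, len(a), len(b))
            )
            continue
        _, p = welch_t_test(a, b)
        ddct = float(a.mean() - b.mean())
        results.append(
            DeltaCtResult(
                assay_id=assay,
                mean_dct_a=float(a.mean()),
                mean_dct_b=float(b.mean()),
                ddct=ddct,
                fold_change=float(2.0 ** (-ddct)),
                p_raw=p,
                p_adj=np.nan,
                n_a=len(a),
                n_b=len(b),
            )
        )
        p_raw.append(p)
        testable.append(len(results) - 1)
    if p_raw:
        adj = benjamini_hochberg(p_raw)
        for i, a_p in zip(testable, adj):
            results[i].p_adj = float(a_p)
    return results


def concordance_with_array(
    dct_results: Sequence[DeltaCtResult],
    de_records: Sequence[DifferentialRecord],
    alpha: float = 0.05,
) -> list[DeltaCtResult]:
    """Classify each qPCR result against the array call for the same feature.

    significant_same_direction: adjusted P < alpha and the qPCR fold change
    agrees in direction with the array call; same_direction_ns: direction
    agrees without significance; inverse: directions disagree;
    not_evaluable: the assay is absent from the array table or has no
    usable test.
    """
    array_dir = {r.feature_id: r for r in de_records}
    out = []
    for res in dct_results:
        rec = array_dir.get(res.assay_id)
        if rec is None or not np.isfinite(res.p_adj) or res.fold_change == 1.0:
            concordance = NOT_EVALUABLE
        else:
            array_sign = 1.0 if rec.log2fc > 0 else -1.0
            qpcr_sign = 1.0 if res.fold_change > 1.0 else -1.0
            if array_sign != qpcr_sign:
                concordance = INVERSE
            elif res.p_adj < alpha:
                concordance = SIGNIFICANT_SAME
            else:
                concordance = SAME_NS
        out.append(
            DeltaCtResult(
                assay_id=res.assay_id,
                mean_dct_a=res.mean_dct_a,
                mean_dct_b=res.mean_dct_b,
                ddct=res.ddct,
                fold_change=res.fold_change,
                p_raw=res.p_raw,
                p_adj=res.p_adj,
                n_a=res.n_a,
                n_b=res.n_b,
                concordance=concordance,
            )
        )
    return out


def results_to_frame(results: Sequence[DeltaCtResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.assay_id,
                r.mean_dct_a,
                r.mean_dct_b,
                r.ddct,
                r.fold_change,
                r.p_raw,
                r.p_adj,
                r.n_a,
                r.n_b,
                r.concordance,
            )
            for r in results
        ],
        columns=[
            "assay_id",
            "mean_dct_a",
            "mean_dct_b",
            "ddct",
            "fold_change",
            "p_raw",
            "p_adj",
            "n_a",
            "n_b",
            "concordance",
        ],
    )
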