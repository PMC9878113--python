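"""ROC/AUC evaluation of heart-failure markers and marker+miRNA panels.

Each panel (e.g. NT-proBNP alone, or NT-proBNP plus one miRNA's log2
expression) is fitted as an in-sample logistic regression of the class
label (TGA-RV vs TGA-LV); the AUC of the fitted linear predictor measures
discrimination, and the panel's significance is the model-vs-null test on
the deviance.  Two test modes are offered: the likelihood-ratio chi-square
(default) and a "deviance F" variant that scales the deviance drop by the
residual deviance per degree of freedom.  Single-feature stratum screens
(overt heart failure, death) reuse the differential-expression machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .diffexpr import benjamini_hochberg, call_differential, records_to_frame
from .io import ExpressionMatrix, SchemaError


@dataclass
class LogisticFit:
    scores: pd.Series  # linear predictor per sample
    coefficients: dict[str, float]
    deviance: float
    n_params: int
    n_samples: int
    labels: pd.Series
    separable: bool = False


@dataclass
class RocResult:
    panel: list[str]
    auc: float
    p_raw: float
    p_adj: float
    n_pos: int
    n_neg: int
    model_coefficients: dict[str, float]


@dataclass
class StratumDeResult:
    feature_id: str
    stratum: str
    fold_change: float
    p_raw: float
    p_adj: float
    direction: str


def auc_from_scores(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie) (normalized Mann-Whitney U)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("AUC requires exactly two classes present")
    return float(roc_auc_score(labels, scores))


def fit_logistic_panel(
    features: pd.DataFrame,
    labels: pd.Series,
    regularization: float = 0.0,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of labels on the panel variables.

    Samples with any missing panel value are dropped (and counted); if the
    unpenalized fit fails to converge because the classes are linearly
    separable, the fit is retried with a small ridge penalty so a ranking
    score is still produced (the AUC of a separable panel is determined by
    the ranking regardless of penalty).
    """
    keep = features.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} samples with missing panel values")
    X = features.loc[keep].astype(float)
    y = labels.loc[X.index].astype(int)
    if y.nunique() != 2:
        raise SchemaError("panel fit requires both classes present")
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise SchemaError("panel fit requires >= 3 samples per class")
    Xc = sm.add_constant(X, has_constant="add")
    separable = False
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    if regularization > 0:
        res = _ridge_logit(X, y, regularization)
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(maxiter=200)
            bad = (
                not np.all(np.isfinite(res.params))
                or np.abs(res.params).max() > 1e6
                or res.deviance < 1e-6  # zero deviance: classes separated
            )
        except Exception:
            bad = True
            res = None
        if bad:
            separable = True
            warnings.warn("separable panel; refitting with a small ridge penalty")
            res = _ridge_logit(X, y, 1e-4)
    params = pd.Series(res.params, index=Xc.columns)
    scores = Xc.to_numpy() @ params.to_numpy()
    mu = 1.0 / (1.0 + np.exp(-scores))
    eps = 1e-12
    deviance = -2.0 * float(
        np.sum(y * np.log(np.clip(mu, eps, 1)) + (1 - y) * np.log(np.clip(1 - mu, eps, 1)))
    )
    return LogisticFit(
        scores=pd.Series(scores, index=X.index),
        coefficients=dict(params),
        deviance=deviance,
        n_params=Xc.shape[1],
        n_samples=len(y),
        labels=y,
        separable=separable,
    )


def _ridge_logit(X: pd.DataFrame, y: pd.Series, alpha: float):
    Xc = sm.add_constant(X, has_constant="add")
    # no penalty on the intercept
    pen = np.full(Xc.shape[1], alpha)
    pen[0] = 0.0
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit_regularized(alpha=pen, L1_wt=0.0, maxiter=500)


def panel_significance(
    fit_full: LogisticFit, fit_null: LogisticFit, mode: str = "lr"
) -> float:
    """Model-vs-null p-value for nested logistic fits.

    ``mode="lr"``: likelihood-ratio chi-square on the deviance drop.
    ``mode="deviance_f"``: the deviance drop per added parameter divided by
    the full model's residual deviance per residual degree of freedom,
    referred to an F distribution — an analog of the regression F-test on
    the deviance scale.
    """
    if fit_full.n_samples != fit_null.n_samples:
        raise SchemaError("nested models must be fitted on identical samples")
    df = fit_full.n_params - fit_null.n_params
    drop = max(fit_null.deviance - fit_full.deviance, 0.0)
    if df < 0 or (df == 0 and drop > 1e-9):
        raise SchemaError("models are not nested (full must extend the null)")
    if df == 0:
        return 1.0  # identical models: no deviance to explain
    if mode == "lr":
        return float(stats.chi2.sf(drop, df))
    if mode == "deviance_f":
        resid_df = fit_full.n_samples - fit_full.n_params
        scale = fit_full.deviance / resid_df if resid_df > 0 else np.nan
        if not np.isfinite(scale) or scale <= 0:
            return float(stats.chi2.sf(drop, df))  # saturated full model: fall back
        f = (drop / df) / scale
        return float(stats.f.sf(f, df, resid_df))
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_panels(
    marker_table: pd.DataFrame,
    labels: pd.Series,
    markers: Sequence[str],
    mirna_matrix: ExpressionMatrix | None = None,
    mirnas: Sequence[str] = (),
    mode: str = "lr",
) -> pd.DataFrame:
    """Marker-alone and marker+miRNA panel AUC table.

    For each clinical marker, evaluates the marker alone and the marker
    combined with each candidate miRNA's log2 expression; p-values are the
    model-vs-null tests, BH-adjusted per marker across its miRNA panels
    (mirroring a per-marker panel family).
    """
    rows = []
    for marker in markers:
        base = marker_table[[marker]]
        fit_m = fit_logistic_panel(base, labels)
        # the null is refitted on exactly the samples the marker fit used
        null_aligned = _refit_null(fit_m)
        auc_m = auc_from_scores(fit_m.scores, fit_m.labels)
        p_m = panel_significance(fit_m, null_aligned, mode=mode)
        rows.append(
            RocResult([marker], auc_m, p_m, np.nan, int(fit_m.labels.sum()), int((1 - fit_m.labels).sum()), fit_m.coefficients)
        )
        mirna_results = []
        if mirna_matrix is not None:
            for mirna in mirnas:
                expr = mirna_matrix.values.loc[mirna]
                combo = marker_table[[marker]].copy()
                combo[mirna] = expr.reindex(combo.index)
                fit_c = fit_logistic_panel(combo, labels)
                p_c = panel_significance(fit_c, _refit_null(fit_c), mode=mode)
                mirna_results.append(
                    RocResult(
                        [marker, mirna],
                        auc_from_scores(fit_c.scores, fit_c.labels),
                        p_c,
                        np.nan,
                        int(fit_c.labels.sum()),
                        int((1 - fit_c.labels).sum()),
                        fit_c.coefficients,
                    )
                )
        if mirna_results:
            adj = benjamini_hochberg([r.p_raw for r in mirna_results])
            for r, a in zip(mirna_results, adj):
                r.p_adj = float(a)
        rows.extend(mirna_results)
    return pd.DataFrame(
        [
            ("+".join(r.panel), r.auc, r.p_raw, r.p_adj, r.n_pos, r.n_neg)
            for r in rows
        ],
        columns=["panel", "auc", "p_raw", "p_adj", "n_pos", "n_neg"],
    )


def _refit_null(fit: LogisticFit) -> LogisticFit:
    """Intercept-only fit on exactly the samples used by ``fit``."""
    y = fit.labels
    p_hat = y.mean()
    deviance = -2.0 * float(
        len(y) * (p_hat * np.log(p_hat) + (1 - p_hat) * np.log(1 - p_hat))
    )
    return LogisticFit(
        scores=pd.Series(np.full(len(y), np.log(p_hat / (1 - p_hat))), index=y.index),
        coefficients={"const": float(np.log(p_hat / (1 - p_hat)))},
        deviance=deviance,
        n_params=1,
        n_samples=len(y),
        labels=y,
    )


def stratum_screen(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    stratum: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-feature DE screen for a clinical stratum (overt_hf or death).

    Runs the standard t-test/fold-change machinery with stratum-positive
    patients as group A and stratum-negative patients as group B.  miRNA
    screens are read on raw p (small strata preclude FDR-significant
    single-miRNA calls); mRNA screens use the adjusted p + fold-change
    threshold.  Control samples are excluded: strata are patient traits.
    """
    if stratum not in ("overt_hf", "death"):
        raise ValueError(f"unknown stratum {stratum!r}")
    meta = metadata[metadata["group"] != "control"]
    flags = meta.set_index("sample_id")[stratum]
    in_matrix = [s for s in matrix.sample_ids if s in flags.index]
    pos = [s for s in in_matrix if flags[s] is True or flags[s] == 1]
    neg = [s for s in in_matrix if not (flags[s] is True or flags[s] == 1)]
    if not pos or not neg:
        raise SchemaError(f"stratum {stratum!r} has an empty class")
    if min(len(pos), len(neg)) < 3:
        warnings.warn(f"stratum {stratum!r} has a class with < 3 samples; power is very low")
    records = call_differential(matrix, pos, neg, fc_threshold=fc_threshold, alpha=alpha)
    frame = records_to_frame(records)
    frame.insert(1, "stratum", stratum)
    return frame[["feature_id", "stratum", "fold_change", "p_raw", "p_adj", "direction"]]
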