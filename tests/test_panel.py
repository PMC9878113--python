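import itertools

import numpy as np
import pandas as pd
import pytest

from tgamir.io import SchemaError
from tgamir.panel import (
    auc_from_scores,
    evaluate_panels,
    fit_logistic_panel,
    panel_significance,
    stratum_screen,
)
from tgamir.preprocess import log2_transform, quantile_normalize


def auc_brute_force(scores, labels):
    """Exhaustive positive-negative pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        for sp, sn in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_from_scores([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_worked_example_half(self):
        assert auc_from_scores([3, 1, 2, 4], [0, 1, 0, 1]) == 0.5

    def test_all_tied_half(self):
        assert auc_from_scores([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            auc_from_scores([1, 2, 3], [1, 1, 1])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
            assert auc_from_scores(scores, labels) == pytest.approx(
                auc_brute_force(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance_and_complement(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        a = auc_from_scores(scores, labels)
        assert auc_from_scores(np.exp(scores), labels) == pytest.approx(a)
        assert auc_from_scores(-scores, labels) == pytest.approx(1.0 - a)


class TestLogisticPanel:
    def labels(self, n):
        return pd.Series([0] * (n // 2) + [1] * (n - n // 2), index=[f"s{i}" for i in range(n)])

    def test_constant_predictor_auc_half(self):
        y = self.labels(12)
        X = pd.DataFrame({"flat": np.ones(12)}, index=y.index)
        fit = fit_logistic_panel(X, y)
        assert auc_from_scores(fit.scores, fit.labels) == 0.5

    def test_separating_predictor_auc_one(self):
        y = self.labels(12)
        X = pd.DataFrame({"x": np.where(y == 1, 5.0, -5.0) + np.arange(12) * 0.01}, index=y.index)
        with pytest.warns(UserWarning, match="separable"):
            fit = fit_logistic_panel(X, y)
        assert auc_from_scores(fit.scores, fit.labels) == 1.0

    def test_combination_beats_singles(self):
        # two weak additive predictors: together they separate better
        rng = np.random.default_rng(2)
        n = 200
        y = pd.Series(rng.integers(0, 2, n), index=[f"s{i}" for i in range(n)])
        signal = y.to_numpy() * 1.0
        x1 = signal + rng.normal(scale=1.5, size=n)
        x2 = signal + rng.normal(scale=1.5, size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2}, index=y.index)
        auc_both = auc_from_scores(fit_logistic_panel(X, y).scores, y)
        auc_1 = auc_from_scores(fit_logistic_panel(X[["x1"]], y).scores, y)
        auc_2 = auc_from_scores(fit_logistic_panel(X[["x2"]], y).scores, y)
        assert auc_both > max(auc_1, auc_2)

    def test_missing_samples_dropped(self):
        y = self.labels(14)
        x = np.linspace(-1, 1, 14)
        x[0] = np.nan
        X = pd.DataFrame({"x": x}, index=y.index)
        with pytest.warns(UserWarning, match="missing"):
            fit = fit_logistic_panel(X, y)
        assert fit.n_samples == 13

    def test_noise_variable_barely_moves_auc(self):
        rng = np.random.default_rng(3)
        n = 500
        y = pd.Series(rng.integers(0, 2, n), index=[f"s{i}" for i in range(n)])
        x = y.to_numpy() + rng.normal(scale=1.0, size=n)
        X1 = pd.DataFrame({"x": x}, index=y.index)
        X2 = X1.assign(noise=rng.normal(size=n))
        a1 = auc_from_scores(fit_logistic_panel(X1, y).scores, y)
        a2 = auc_from_scores(fit_logistic_panel(X2, y).scores, y)
        assert abs(a2 - a1) < 0.1


class TestPanelSignificance:
    def fits(self, effect, n=60, seed=4):
        rng = np.random.default_rng(seed)
        y = pd.Series(rng.integers(0, 2, n), index=[f"s{i}" for i in range(n)])
        x = effect * y.to_numpy() + rng.normal(size=n)
        X = pd.DataFrame({"x": x}, index=y.index)
        full = fit_logistic_panel(X, y)
        from tgamir.panel import _refit_null

        return full, _refit_null(full)

    def test_null_effect_large_p(self):
        full, null = self.fits(effect=0.0)
        assert panel_significance(full, null) > 0.05

    def test_identical_models_p_one(self):
        full, null = self.fits(effect=0.5)
        assert panel_significance(null, null) == pytest.approx(1.0)

    def test_strong_effect_small_p_both_modes(self):
        full, null = self.fits(effect=3.0, n=31)
        assert panel_significance(full, null, mode="lr") < 0.01
        assert panel_significance(full, null, mode="deviance_f") < 0.01

    def test_non_nested_rejected(self):
        full, null = self.fits(effect=1.0)
        with pytest.raises(SchemaError):
            panel_significance(null, full)


class TestEvaluatePanels:
    def test_marker_and_combined_panels(self, default_bundle):
        meta = default_bundle.metadata
        patients = meta[meta["group"] != "control"].set_index("sample_id")
        labels = (patients["group"] == "TGA_RV").astype(int)
        marker_table = patients[["ntprobnp", "hstnt", "egfr"]]
        norm = log2_transform(quantile_normalize(default_bundle.mirna))
        norm_pat = norm.subset_samples(list(patients.index))
        mirnas = norm_pat.feature_ids[:3]
        table = evaluate_panels(
            marker_table, labels, ["ntprobnp", "hstnt"], norm_pat, mirnas
        )
        # one marker-alone row plus one row per miRNA, for each marker
        assert len(table) == 2 * (1 + len(mirnas))
        assert ((table["auc"] >= 0) & (table["auc"] <= 1)).all()
        combined = table[table["panel"].str.contains("\\+")]
        assert combined["p_adj"].notna().all()

    def test_informative_mirna_lifts_marker_auc(self, default_bundle):
        # plant a clean RV/LV discriminator and check the combined panel wins
        meta = default_bundle.metadata
        patients = meta[meta["group"] != "control"].set_index("sample_id")
        labels = (patients["group"] == "TGA_RV").astype(int)
        marker_table = patients[["ntprobnp"]]
        norm = log2_transform(quantile_normalize(default_bundle.mirna))
        norm_pat = norm.subset_samples(list(patients.index))
        boosted = norm_pat.values.copy()
        boosted.loc[boosted.index[0]] = labels.reindex(boosted.columns).to_numpy() * 3.0 + \
            np.random.default_rng(5).normal(scale=0.5, size=boosted.shape[1])
        norm_pat.values.iloc[:, :] = boosted
        table = evaluate_panels(marker_table, labels, ["ntprobnp"], norm_pat, [boosted.index[0]])
        auc_alone = table.loc[table["panel"] == "ntprobnp", "auc"].iloc[0]
        auc_combo = table.loc[table["panel"] != "ntprobnp", "auc"].iloc[0]
        assert auc_combo > auc_alone
        assert auc_combo > 0.9


class TestStratumScreen:
    @pytest.fixture(scope="class")
    def low_noise_bundle(self):
        from tgamir.simulate import SimulationConfig, generate_bundle

        # a single planted overt-HF miRNA under low noise: the raw-p screen
        # should put it first
        cfg = SimulationConfig(
            seed=17, noise_sd_log2=0.1, n_mirna=150, n_mrna=50,
            n_hf_informative_mirna=1,
        )
        return generate_bundle(cfg)

    def test_planted_hf_mirna_attains_minimum_raw_p(self, low_noise_bundle):
        norm = log2_transform(low_noise_bundle.mirna)
        screen = stratum_screen(norm, low_noise_bundle.metadata, "overt_hf")
        (planted,) = low_noise_bundle.truth.hf_informative_markers
        best = screen.loc[screen["p_raw"].idxmin(), "feature_id"]
        assert best == planted

    def test_label_permutation_destroys_the_signal(self, low_noise_bundle):
        norm = log2_transform(low_noise_bundle.mirna)
        meta = low_noise_bundle.metadata.copy()
        rng = np.random.default_rng(6)
        patients = meta["group"] != "control"
        meta.loc[patients, "overt_hf"] = rng.permutation(meta.loc[patients, "overt_hf"].to_numpy())
        screen = stratum_screen(norm, meta, "overt_hf")
        (planted,) = low_noise_bundle.truth.hf_informative_markers
        p_planted = screen.loc[screen["feature_id"] == planted, "p_raw"].iloc[0]
        assert p_planted > screen["p_raw"].min()

    def test_empty_class_rejected(self, default_bundle):
        norm = log2_transform(quantile_normalize(default_bundle.mirna))
        meta = default_bundle.metadata.copy()
        meta["death"] = False
        with pytest.raises(SchemaError, match="empty class"):
            stratum_screen(norm, meta, "death")

    def test_unknown_stratum_rejected(self, default_bundle):
        with pytest.raises(ValueError, match="stratum"):
            stratum_screen(default_bundle.mirna, default_bundle.metadata, "age")
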