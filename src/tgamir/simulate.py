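"""Synthetic study-bundle generator with planted, recoverable structure.

Emulates a three-group blood transcriptomics design (TGA-RV, TGA-LV,
control; 16 samples each by default) profiled on a miRNA and an mRNA array
platform, together with clinical metadata, a 3'UTR binding-site table and
qPCR Ct tables.  Everything downstream of the wet lab is exercised against
bundles from this module, whose ground truth (which features are shifted,
which miRNA-mRNA pairs are coupled) is returned alongside the data.

Generative model
----------------
Per-feature baseline log2 intensities are normal (raw intensities
log-normal).  Differentially expressed features receive additive log2
shifts per patient group; a configurable fraction of miRNA effects is
shared between TGA-RV and TGA-LV, the remainder is RV-specific, mirroring
cohorts where the systemic-right-ventricle signal dominates.  Each planted
regulatory pair ties an mRNA to its miRNA through the miRNA's per-sample
normal scores z (the rank-inverse-normal transform of its log2 column):
the mRNA's structural part is -gain * (r z + sqrt(1-r^2) eta) with eta an
independent standard normal and r = 2 sin(pi * coupling_strength / 6),
the bivariate-normal Pearson equivalent of the target Spearman.  In the
noise-free limit the pair's Spearman correlation is -coupling_strength
exactly; measurement noise (noise_sd_log2) attenuates it by the factor
1/sqrt(1 + (noise_sd/gain)^2), so the empirical correlation converges to
the target monotonically as noise shrinks.  Because z is a monotone
transform of the miRNA column, a differentially expressed miRNA drags its
coupled mRNA in the opposite direction across groups as well.  Detection
dropout is logistic in log2 intensity, so weak features fail the
detection call more often, as on real arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GROUPS, METADATA_COLUMNS, BindingSiteTable, ExpressionMatrix


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study bundle.

    Defaults follow the emulated study design: 3 groups x 16 samples,
    log2-scale group shifts of at least ~0.585 (a 1.5-fold change, the
    screening threshold) drawn up to 2.0, planted miRNA-mRNA couplings with
    target |Spearman rho| 0.7, and 10% detection dropout.  Feature counts
    default to a scaled-down platform (300 miRNA probes, 1000 mRNA
    features).
    """

    n_per_group: int = 16
    n_mirna: int = 300
    n_mrna: int = 1000
    frac_de_mirna: float = 0.10
    frac_de_mrna: float = 0.05
    effect_log2fc: float = 0.585
    max_effect_log2fc: float = 2.0
    shared_effect_fraction: float = 0.5
    n_regulatory_pairs: int = 20
    coupling_strength: float = 0.7
    coupling_gain_log2: float = 1.0
    decoy_site_factor: int = 5
    dropout_rate: float = 0.1
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0
    n_overt_hf: int = 4
    n_death: int = 4
    n_hf_informative_mirna: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.frac_de_mirna < 1 or not 0 <= self.frac_de_mrna < 1:
            raise ConfigError("DE fractions must lie in [0, 1)")
        if self.effect_log2fc <= 0:
            raise ConfigError("effect_log2fc must be positive")
        if not 0 <= self.coupling_strength <= 1:
            raise ConfigError("coupling_strength must lie in [0, 1]")
        if self.coupling_strength > 0.99:
            raise ConfigError(
                "coupling_strength > 0.99 is infeasible: the implied Pearson "
                "correlation approaches 1 and no finite coupling scale attains it"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.noise_sd_log2 <= 0:
            raise ConfigError("noise_sd_log2 must be positive")
        if self.n_regulatory_pairs > self.n_mirna * self.n_mrna:
            raise ConfigError("more regulatory pairs than miRNA x mRNA combinations")
        if self.n_overt_hf > 2 * self.n_per_group or self.n_death > 2 * self.n_per_group:
            raise ConfigError("stratum sizes exceed the patient count")


@dataclass
class GroundTruth:
    """Planted structure of one bundle, for parameter-recovery testing."""

    de_mirna: dict[str, dict[str, float]]  # feature -> {group: true log2FC vs control}
    de_mrna: dict[str, dict[str, float]]
    regulatory_pairs: set[tuple[str, str, float]]  # (mirna, mrna, planted_rho < 0)
    hf_informative_markers: list[str] = field(default_factory=list)


@dataclass
class Bundle:
    """One complete synthetic study: matrices, metadata, sites, truth."""

    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    metadata: pd.DataFrame
    sites: BindingSiteTable
    truth: GroundTruth
    config: SimulationConfig


def _rng(seed: int, stream: int) -> np.random.Generator:
    # fixed per-section substreams keep draws independent of generation order
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal conversion: rho_s = (6/pi) asin(r/2)."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _norm_ppf(q: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf(q)


def _sample_ids(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    ids, groups = [], []
    for g, prefix in zip(GROUPS, ("RV", "LV", "CTL")):
        for i in range(config.n_per_group):
            ids.append(f"{prefix}{i + 1:02d}")
            groups.append(g)
    return ids, pd.Series(groups, index=ids, name="group")


def _draw_effects(
    rng: np.random.Generator, n_features: int, n_de: int, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Choose DE features and their per-group log2 shifts vs control."""
    if n_de == 0:
        empty = np.array([], dtype=int)
        return empty, np.array([]), np.array([])
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    mag = rng.uniform(config.effect_log2fc, config.max_effect_log2fc, size=n_de)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    rv = mag * sign
    shared = rng.random(n_de) < config.shared_effect_fraction
    lv = np.where(shared, rv, 0.0)  # non-shared effects are RV-specific
    return de_idx, rv, lv


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Generate one synthetic study bundle; identical config => identical bundle."""
    config.validate()
    sample_ids, groups = _sample_ids(config)
    n_samples = len(sample_ids)
    group_arr = groups.to_numpy()

    mirna_ids = [f"sim-miR-{i + 1:04d}" for i in range(config.n_mirna)]
    mrna_ids = [f"SIMG{i + 1:05d}" for i in range(config.n_mrna)]

    # --- miRNA platform -----------------------------------------------------
    rng_mi = _rng(config.seed, 1)
    mu_mi = rng_mi.normal(config.baseline_mean_log2, config.baseline_sd_log2, config.n_mirna)
    n_de_mi = int(round(config.frac_de_mirna * config.n_mirna))
    de_mi_idx, rv_mi, lv_mi = _draw_effects(rng_mi, config.n_mirna, n_de_mi, config)
    shift_mi = np.zeros((config.n_mirna, n_samples))
    shift_mi[np.ix_(de_mi_idx, group_arr == "TGA_RV")] += rv_mi[:, None]
    shift_mi[np.ix_(de_mi_idx, group_arr == "TGA_LV")] += lv_mi[:, None]
    log2_mi = (
        mu_mi[:, None]
        + shift_mi
        + rng_mi.normal(0.0, config.noise_sd_log2, (config.n_mirna, n_samples))
    )

    # --- mRNA platform ------------------------------------------------------
    rng_m = _rng(config.seed, 2)
    mu_m = rng_m.normal(config.baseline_mean_log2, config.baseline_sd_log2, config.n_mrna)
    n_de_m = int(round(config.frac_de_mrna * config.n_mrna))
    de_m_idx, rv_m, lv_m = _draw_effects(rng_m, config.n_mrna, n_de_m, config)

    # planted regulatory pairs: DE miRNAs coupled to mRNAs outside the
    # independently-DE mRNA set, so each platform's truth stays disjoint
    rng_pairs = _rng(config.seed, 3)
    free_mrna = np.setdiff1d(np.arange(config.n_mrna), de_m_idx)
    n_pairs = min(config.n_regulatory_pairs, len(free_mrna))
    pair_mrna_idx = rng_pairs.choice(free_mrna, size=n_pairs, replace=False)
    mirna_pool = de_mi_idx if len(de_mi_idx) else np.arange(config.n_mirna)
    pair_mirna_idx = rng_pairs.choice(mirna_pool, size=n_pairs, replace=True)

    shift_m = np.zeros((config.n_mrna, n_samples))
    shift_m[np.ix_(de_m_idx, group_arr == "TGA_RV")] += rv_m[:, None]
    shift_m[np.ix_(de_m_idx, group_arr == "TGA_LV")] += lv_m[:, None]
    eps = rng_m.normal(0.0, config.noise_sd_log2, (config.n_mrna, n_samples))
    log2_m = mu_m[:, None] + shift_m + eps

    r_target = _spearman_to_pearson(config.coupling_strength)
    regulatory_pairs: set[tuple[str, str, float]] = set()
    for mi_i, m_i in zip(pair_mirna_idx, pair_mrna_idx):
        x = log2_mi[mi_i]
        if r_target > 0:
            # normal scores of the miRNA column: monotone in x, exactly
            # standard-normal quantiles, so the Spearman target is hit
            # regardless of the miRNA's group-cluster structure
            ranks = np.argsort(np.argsort(x)) + 1.0
            z = _norm_ppf((ranks - 0.5) / n_samples)
            eta = rng_pairs.standard_normal(n_samples)
            struct = r_target * z + np.sqrt(1.0 - r_target**2) * eta
            log2_m[m_i] = mu_m[m_i] - config.coupling_gain_log2 * struct + eps[m_i]
        regulatory_pairs.add(
            (mirna_ids[mi_i], mrna_ids[m_i], -float(config.coupling_strength))
        )

    # --- detection dropout: logistic in log2 intensity ----------------------
    def detection(log2_values: np.ndarray, stream: int) -> np.ndarray:
        rng_d = _rng(config.seed, stream)
        if config.dropout_rate == 0:
            return np.ones_like(log2_values, dtype=bool)
        med = np.median(log2_values)
        p_drop = np.clip(
            2.0 * config.dropout_rate / (1.0 + np.exp((log2_values - med) / 1.5)), 0.0, 1.0
        )
        return rng_d.random(log2_values.shape) >= p_drop

    det_mi = detection(log2_mi, 4)
    det_m = detection(log2_m, 5)

    mirna = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2_mi), index=mirna_ids, columns=sample_ids),
        pd.DataFrame(det_mi, index=mirna_ids, columns=sample_ids),
        scale="raw",
        platform="miRNA",
    )
    mrna = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2_m), index=mrna_ids, columns=sample_ids),
        pd.DataFrame(det_m, index=mrna_ids, columns=sample_ids),
        scale="raw",
        platform="mRNA",
    )

    # --- binding sites: one row per planted pair plus decoys ----------------
    rng_s = _rng(config.seed, 6)
    site_rows = []
    planted_pairs = {(a, b) for a, b, _ in regulatory_pairs}
    for mirna_id, mrna_id in sorted(planted_pairs):
        start = int(rng_s.integers(0, 2000))
        site_rows.append((mirna_id, mrna_id, "UTR3", start, start + 7))
    n_decoys = config.decoy_site_factor * max(len(planted_pairs), 1)
    made = set(planted_pairs)
    while len(site_rows) < len(planted_pairs) + n_decoys:
        pair = (
            mirna_ids[int(rng_s.integers(0, config.n_mirna))],
            mrna_ids[int(rng_s.integers(0, config.n_mrna))],
        )
        if pair in made:
            continue
        made.add(pair)
        start = int(rng_s.integers(0, 2000))
        site_rows.append((*pair, "UTR3", start, start + 7))
    sites = BindingSiteTable(pd.DataFrame(site_rows, columns=BindingSiteTable.COLUMNS))

    # --- clinical metadata --------------------------------------------------
    rng_c = _rng(config.seed, 7)
    patients = [s for s, g in zip(sample_ids, group_arr) if g != "control"]
    ohf = set(rng_c.choice(patients, size=config.n_overt_hf, replace=False))
    death = set(rng_c.choice(patients, size=config.n_death, replace=False))
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group_arr,
            "overt_hf": [s in ohf if g != "control" else False for s, g in zip(sample_ids, group_arr)],
            "death": [s in death if g != "control" else False for s, g in zip(sample_ids, group_arr)],
        }
    )
    # heart-failure labs for patients only; controls keep empty cells
    n_pat = len(patients)
    labs = pd.DataFrame(
        {
            "ntprobnp": np.exp(rng_c.normal(np.log(150.0), 0.8, n_pat)),
            "hstnt": np.exp(rng_c.normal(np.log(4.0), 0.6, n_pat)),
            "egfr": rng_c.normal(105.0, 20.0, n_pat),
        },
        index=patients,
    )
    for col in ("ntprobnp", "hstnt", "egfr"):
        meta[col] = meta["sample_id"].map(labs[col])

    # --- overt-HF informative miRNAs ---------------------------------------
    hf_informative: list[str] = []
    if config.n_hf_informative_mirna > 0 and ohf:
        non_de = np.setdiff1d(np.arange(config.n_mirna), de_mi_idx)
        hf_idx = rng_c.choice(non_de, size=config.n_hf_informative_mirna, replace=False)
        ohf_cols = [sample_ids.index(s) for s in sorted(ohf)]
        vals = mirna.values.to_numpy()
        vals[np.ix_(hf_idx, ohf_cols)] *= 2.0 ** config.effect_log2fc
        mirna.values.iloc[:, :] = vals
        hf_informative = [mirna_ids[i] for i in hf_idx]

    truth = GroundTruth(
        de_mirna={
            mirna_ids[i]: {"TGA_RV": float(rv), "TGA_LV": float(lv)}
            for i, rv, lv in zip(de_mi_idx, rv_mi, lv_mi)
        },
        de_mrna={
            mrna_ids[i]: {"TGA_RV": float(rv), "TGA_LV": float(lv)}
            for i, rv, lv in zip(de_m_idx, rv_m, lv_m)
        },
        regulatory_pairs=regulatory_pairs,
        hf_informative_markers=hf_informative,
    )
    return Bundle(mirna=mirna, mrna=mrna, metadata=meta, sites=sites, truth=truth, config=config)


# ---------------------------------------------------------------------------
# qPCR Ct emulation


def generate_ct_table(
    bundle: Bundle,
    assays: Sequence[str],
    reference_id: str = "RNU6B",
    ct_intercept: float = 36.0,
    ct_slope: float = 1.0,
    ct_noise_sd: float = 0.0,
    reference_log2_level: float = 10.0,
    censor_fraction: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emulate single-assay qPCR: Ct = intercept - slope * log2(expression).

    The reference assay is generated at a group-invariant level (an
    endogenous control must be stable), and ``censor_fraction`` of the
    non-reference Ct values is pushed above the usability gate (Ct > 35) to
    exercise gating downstream.  Returns a long table with columns
    sample_id, assay_id, ct.
    """
    missing = [a for a in assays if a not in bundle.mirna.feature_ids]
    if missing:
        raise ConfigError(f"assays not in bundle miRNA features: {missing}")
    if reference_id in bundle.truth.de_mirna:
        raise ConfigError(
            f"reference assay {reference_id!r} is a planted DE feature; "
            "the endogenous control must be group-stable"
        )
    rng = _rng(bundle.config.seed if seed is None else seed, 8)
    sample_ids = bundle.mirna.sample_ids
    log2_vals = np.log2(bundle.mirna.values.loc[list(assays)].to_numpy())
    rows = []
    for sample_j, sample in enumerate(sample_ids):
        ref_ct = (
            ct_intercept
            - ct_slope * reference_log2_level
            + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
        )
        rows.append((sample, reference_id, float(ref_ct)))
        for assay_i, assay in enumerate(assays):
            ct = ct_intercept - ct_slope * log2_vals[assay_i, sample_j]
            if ct_noise_sd > 0:
                ct += rng.normal(0.0, ct_noise_sd)
            rows.append((sample, assay, float(ct)))
    table = pd.DataFrame(rows, columns=["sample_id", "assay_id", "ct"])
    if censor_fraction > 0:
        non_ref = table.index[table["assay_id"] != reference_id]
        n_censor = int(round(censor_fraction * len(non_ref)))
        hit = rng.choice(non_ref, size=n_censor, replace=False)
        table.loc[hit, "ct"] = 35.0 + rng.uniform(0.5, 5.0, size=n_censor)
    return table
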