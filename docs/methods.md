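# Methods

This note records the statistical procedures the package implements, the
choices made where the underlying protocol leaves room, and what the
synthetic-cohort tests do and do not establish about real data.

## Preprocessing

**Detection filter.** A feature is kept when its detection rate (fraction of
samples with a positive detection call) reaches `min_rate` (default 0.5) in
at least one group (`mode="any_group"`). The stricter reading — required in
*every* group — is available as `mode="all_groups"`. The permissive default
matches common array practice, where a transcript confined to one clinical
group is biologically interesting rather than technical noise. The filter is
idempotent, and undetected cells keep their measured intensity: detection
calls drive the filter only, never imputation, because no imputation step is
part of the protocol being implemented.

**Quantile normalization.** The reference distribution is the vector of
row-wise means of the per-sample sorted columns; each cell receives the
reference value at its within-column rank. Ties within a column receive the
mean of the reference values over the tied span, so tied inputs remain tied
and within-column rank order is preserved exactly. This tie rule is stated
explicitly because results differ across conventions. A single-feature
matrix is returned unchanged with a warning. One known pathology is worth
noting: when technical noise is far smaller than the spacing between
feature baselines, a feature occupies the same rank in every column and its
normalized values become (near-)constant, which destabilizes downstream
t-statistics; this matters only in near-noiseless synthetic scenarios, and
the relevant tests therefore screen on log2 data directly.

**log2 transform.** `log2(value + offset)` with offset default 1.0 to guard
zeros; the offset is configurable because the source protocol does not state
one. **Clustering.** Sample/feature dendrograms use average linkage (UPGMA)
on Euclidean distances via scipy; items are sorted lexicographically by id
first so distance ties resolve deterministically. Heights are validated
against an O(n³) re-implementation in the tests.

## Differential expression

The test is the unpaired two-tailed t-test on log2 intensities, Welch
variance by default ("pooled" available); whether the original analysis
assumed equal variances is not stated, so the choice is surfaced rather than
hidden — with balanced groups and similar spreads the two coincide. For
features with zero variance in both groups the degenerate limits are used
(equal means → p = 1; unequal → p = 0, flagged). p-values are adjusted by
the Benjamini–Hochberg step-up across all features of one platform and one
comparison that survived the detection filter (delegated to statsmodels; a
literal step-up oracle cross-checks it in the tests). Fold change is the
geometric-mean ratio 2^(mean_A − mean_B) — the only convention consistent
with testing on the log2 scale; a ratio of linear means is deliberately not
offered. A feature is called Lower/Higher only under the dual threshold
adjusted P < 0.05 and FC ≥ 1.5 or ≤ 1/1.5 (exact reciprocal in
computation; the packaged printed tables are checked against the 2-decimal
rounded bound 0.67, which is how a value passing the reciprocal rule prints).

## qPCR relative quantification

Ct values above the gate (default 35 cycles) are unusable: a failing assay
measurement drops that sample for that assay, a failing reference drops the
sample entirely. ΔCt = Ct_assay − Ct_reference per sample (RNU6B default);
group comparison runs the t-test on ΔCt — the additive scale on which the
measurement noise is approximately homoscedastic — rather than on per-sample
2^(−ΔCt), with BH across the assay panel per comparison. ΔΔCt is the
difference of group-mean ΔCt and fold change 2^(−ΔΔCt). Concordance with
the array: `significant_same_direction` when adjusted P < α and the qPCR
fold change agrees in sign (on the log scale) with the array call;
`same_direction_ns` without significance; `inverse` when the directions
disagree; `not_evaluable` when the assay is missing from the array table or
has fewer than two usable samples in a group. One Ct per sample-assay is
modelled; technical replicates and efficiency correction are out of scope.

## Integration network

Candidate pairs are the cross product of direction-called miRNAs and mRNAs,
restricted to opposite directions and to pairs with a 3′UTR binding-site row
(the binding-site table is consumed as data; no target prediction is run).
Each candidate is scored by Spearman correlation (mid-ranks; two-sided p
from the t approximation on n − 2 df) across the pooled samples of all
groups by default — the correlation is meant to capture the dose-response
across the whole cohort, and the sample set is configurable. The retention
gate is ρ ≤ −ρ_threshold (default 0.5) and P < α: the negative sign is
required because the construct is a *repression* network; a permissive mode
(|ρ| ≥ threshold, either sign) exists for sensitivity analysis. Correlation
p-values are not multiplicity-adjusted by default, matching a raw per-pair
P < 0.05 gate; BH across candidates is available as an option. Every
retained edge is re-checked by an independent validator pass, and summaries
report both pair-level counts and distinct-node counts per direction
pattern, without assuming the two coincide.

## Biomarker panels

Panels are fitted as in-sample logistic regressions (statsmodels GLM,
binomial family) of the TGA-RV vs TGA-LV label; samples missing any panel
variable are dropped and counted (controls lack the heart-failure labs
entirely, which restricts marker panels to the patient groups). AUC is
computed from the fitted linear predictor as the normalized Mann–Whitney U
(ties count one half). When the classes are linearly separable the
unpenalized MLE diverges; the fit is then retried with a small ridge penalty
(α = 1e-4, intercept unpenalized) and flagged — the AUC is unaffected
because it depends only on the score ranking. Panel significance is the
model-vs-null test on the deviance: the likelihood-ratio χ² by default, with
a "deviance F" mode (deviance drop per added parameter over residual
deviance per residual df, referred to an F distribution) as an analog of the
regression F-test for users who want that convention; identical models give
p = 1. p-values are BH-adjusted per marker across its miRNA panels. No
cross-validation is applied by default: the in-sample AUC reproduces the
described computation, and with n = 32 and single-variable additions the
optimism is acknowledged rather than corrected. Stratum screens (overt heart
failure, death) reuse the DE machinery on patient samples only; with the
realistic stratum sizes (4 positives) single-feature significance after FDR
is unattainable, so miRNA stratum screens are read on raw p while mRNA
screens use the adjusted-p + fold-change rule.

## Synthetic cohorts

The generator emulates the study design: three groups × 16 samples, a miRNA
platform and a larger mRNA platform (scaled down by default to 300 and
1,000 features so the full Monte-Carlo studies run in seconds; the real
platforms carry ~2,549 and ~50,599 features and scale linearly). Baseline
log2 intensities are per-feature normal (mean 8, sd 2 — raw intensities
log-normal); technical noise is additive normal on the log2 scale (default
sd 0.5). A fraction of features (10% miRNA, 5% mRNA) receives additive
group shifts with magnitudes uniform on [0.585, 2.0] log2 units — bracketing
the screening threshold (log2 1.5 ≈ 0.585) and the fold-change range the
published tables print — with random sign; half the miRNA effects are shared
between TGA-RV and TGA-LV and the rest are RV-specific, reproducing the
qualitative pattern that the RV-specific contrast yields the most calls.

**Couplings.** Each planted repressive pair ties an mRNA to a DE miRNA
through the miRNA's normal scores z (rank-inverse-normal transform of its
log2 column): the mRNA is μ − gain·(r·z + √(1−r²)·η) + ε with η standard
normal, gain default 1.0 log2 unit, and r = 2·sin(π·c/6) — the
bivariate-normal Pearson equivalent of the target Spearman c. Working
through normal scores rather than the raw miRNA column makes the construction
robust to the miRNA's group-cluster structure: in the noise-free limit the
pair's Spearman correlation is −c exactly, and measurement noise attenuates
it by 1/√(1 + (σ_ε/gain)²), converging monotonically to the target as noise
shrinks. Because z is monotone in the miRNA, a DE miRNA drags its coupled
mRNA in the opposite direction across groups, so planted pairs are
discoverable by the DE → network chain. Coupling strengths above 0.99 are
rejected as infeasible (the implied Pearson correlation approaches 1).
Coupled mRNAs are drawn outside the independently-DE mRNA set so the two
kinds of planted structure stay disjoint. The binding-site table contains
one site per planted pair plus five decoy sites per planted pair on random
uncoupled pairs, so the site filter and the correlation gates both do real
work.

**Dropout, metadata, Ct.** Detection dropout is logistic in log2 intensity
(probability 2·d/(1+exp((v−median)/1.5)), overall rate ≈ d), concentrating
missed calls in dim cells as on real arrays. Clinical metadata assigns
overt-HF and death flags to 4 patients each (the realistic stratum sizes)
and log-normal heart-failure labs to patients only; controls keep empty
cells. A configurable number of miRNAs receives an overt-HF-specific shift
as ground truth for the stratum screen. Ct tables follow the affine model
Ct = a − b·log2(expression) (defaults a = 36, b = 1) with Gaussian noise,
a group-invariant reference assay, and an optional censoring fraction pushed
above the 35-cycle gate. All draws derive from one seed through fixed
per-section substreams, so identical configurations give bit-identical
bundles regardless of which sections are consumed.

**What the synthetic tests show — and do not.** Passing parameter recovery
shows the pipeline's gates and statistics behave as designed under the
stated noise model: independent Gaussian log2 noise, additive shifts,
monotone couplings. Real blood arrays add probe-level artifacts, correlated
technical variation, batch effects and age/sex structure, none of which are
simulated; recovery rates measured here are therefore upper bounds on what
identical settings would achieve on real cohorts, not predictions.

## Problem sizes and numerical choices

The default Monte-Carlo studies use 20 seeds (parameter recovery, full-size
default bundles) and 100 seeds × 300 null miRNA features (null control) —
sizes chosen so the entire acceptance run completes in seconds while the
binomial confidence machinery still has resolution. Oracle comparisons
(BH, Spearman, AUC, UPGMA) assert agreement at 1e-12 or better; quantile
normalization asserts exact column-multiset equality. Fixture fold changes
are compared exactly as printed (2 decimals, lower bound 0.67). Stable
mergesort is used wherever ranking feeds a deterministic contract.

## Known limitations

- No moderated (empirical-Bayes) test, covariate adjustment or paired
  designs; the t-test is the protocol.
- The network stage treats mRNA feature ids as gene symbols (an optional
  probe→gene map is the extension point).
- In-sample panel AUCs are optimistic by construction; a CV flag exists but
  defaults off to reproduce the described computation.
- GEO/SOFT, Agilent feature-extraction files and Excel inputs are not
  parsed; the canonical dialect is plain TSV.
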