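"""Validate array calls by emulated RT-qPCR relative quantification.

Ct values are gated at 35 cycles, normalized to the RNU6B reference
(dCt = Ct_assay - Ct_RNU6B, lower dCt = higher abundance), compared by
unpaired t-test with BH adjustment across the assay panel, and classified
for concordance with the array direction.
"""

from tgamir import SimulationConfig, generate_bundle, generate_ct_table, call_differential
from tgamir.diffexpr import NOT_SIGNIFICANT
from tgamir.preprocess import detection_filter, log2_transform, quantile_normalize
from tgamir.qpcr import compare_groups_dct, compute_delta_ct, concordance_with_array, results_to_frame

bundle = generate_bundle(SimulationConfig(seed=1))
filtered, _ = detection_filter(bundle.mirna, bundle.metadata)
norm = log2_transform(quantile_normalize(filtered))
groups = bundle.metadata.set_index("sample_id")["group"]
rv = [s for s in norm.sample_ids if groups[s] == "TGA_RV"]
ctl = [s for s in norm.sample_ids if groups[s] == "control"]
de = call_differential(norm, rv, ctl)

# carry the ten strongest array calls into the qPCR panel
called = sorted((r for r in de if r.direction != NOT_SIGNIFICANT), key=lambda r: -abs(r.log2fc))
assays = [r.feature_id for r in called[:10]]
ct = generate_ct_table(bundle, assays, ct_noise_sd=0.25, censor_fraction=0.02)

dct = compute_delta_ct(ct, reference_id="RNU6B", gate=35.0)
results = compare_groups_dct(dct, rv, ctl)
results = concordance_with_array(results, de)
frame = results_to_frame(results)
print(frame[["assay_id", "ddct", "fold_change", "p_adj", "concordance"]].to_string(index=False))
n_same = (frame["concordance"] == "significant_same_direction").sum()
print(f"\n{n_same}/{len(frame)} assays confirm the array direction with significance")
# ddct < 0 means lower dCt in TGA-RV, i.e. higher abundance; fold change is
# 2^(-ddct), directly comparable to the array fold change.
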