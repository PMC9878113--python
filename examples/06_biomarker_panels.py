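"""Heart-failure-marker ROC panels, alone and augmented with single miRNAs.

Distinguishes TGA-RV from TGA-LV patients (controls lack the clinical
labs).  Each panel is an in-sample logistic regression; its AUC measures
discrimination and the p-value is the likelihood-ratio test against the
intercept-only model, BH-adjusted across each marker's miRNA panels.
"""

from tgamir import SimulationConfig, generate_bundle
from tgamir.panel import evaluate_panels
from tgamir.preprocess import detection_filter, log2_transform, quantile_normalize

bundle = generate_bundle(SimulationConfig(seed=1))
meta = bundle.metadata
patients = meta[meta["group"] != "control"].set_index("sample_id")
labels = (patients["group"] == "TGA_RV").astype(int)

filtered, _ = detection_filter(bundle.mirna, bundle.metadata)
norm = log2_transform(quantile_normalize(filtered)).subset_samples(list(patients.index))

# candidate miRNAs: the ones planted with an RV-specific shift separate best
rv_specific = [f for f, e in bundle.truth.de_mirna.items()
               if e["TGA_RV"] != 0 and e["TGA_LV"] == 0][:3]
table = evaluate_panels(
    patients[["ntprobnp", "hstnt", "egfr"]], labels,
    markers=["ntprobnp", "hstnt", "egfr"],
    mirna_matrix=norm, mirnas=rv_specific,
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nmarker-alone AUCs hover near chance (the synthetic labs carry no "
      "group signal); adding an RV-specific miRNA lifts the panel AUC.")
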