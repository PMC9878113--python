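"""Call differentially expressed miRNAs for the TGA-RV vs control contrast.

Welch t-test on log2 data, Benjamini-Hochberg adjustment across the
platform, and the dual screening threshold: adjusted P < 0.05 with fold
change >= 1.5 or <= 1/1.5.
"""

from tgamir import SimulationConfig, generate_bundle, call_differential
from tgamir.diffexpr import NOT_SIGNIFICANT, records_to_frame
from tgamir.preprocess import detection_filter, log2_transform, quantile_normalize

bundle = generate_bundle(SimulationConfig(seed=1))
filtered, _ = detection_filter(bundle.mirna, bundle.metadata)
norm = log2_transform(quantile_normalize(filtered))

groups = bundle.metadata.set_index("sample_id")["group"]
rv = [s for s in norm.sample_ids if groups[s] == "TGA_RV"]
ctl = [s for s in norm.sample_ids if groups[s] == "control"]
records = call_differential(norm, rv, ctl, fc_threshold=1.5, alpha=0.05)

frame = records_to_frame(records)
called = frame[frame["direction"] != NOT_SIGNIFICANT]
print(f"tested {len(frame)} miRNAs; called {len(called)} "
      f"({(called['direction'] == 'Higher').sum()} Higher, "
      f"{(called['direction'] == 'Lower').sum()} Lower)")
print("\nstrongest calls (|log2FC|):")
top = called.reindex(called["log2fc"].abs().sort_values(ascending=False).index).head(5)
print(top[["feature_id", "fold_change", "p_adj", "direction"]].to_string(index=False))

truth = set(bundle.truth.de_mirna)
print(f"\nplanted DE miRNAs recovered: {len(truth & set(called['feature_id']))}/{len(truth)}")
# Fold change is the geometric-mean ratio 2^(difference of log2 group means),
# so 'Higher' means elevated in TGA-RV relative to controls.
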