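"""Generate one synthetic three-group study bundle and inspect its ground truth.

The bundle mimics a blood transcriptomics cohort: TGA-RV, TGA-LV and
control groups (16 samples each), a miRNA and an mRNA intensity matrix
with detection calls, clinical metadata, and a 3'UTR binding-site table
containing the planted repressive miRNA->mRNA couplings plus decoys.
"""

from tgamir import SimulationConfig, generate_bundle

bundle = generate_bundle(SimulationConfig(seed=1))

print(f"miRNA matrix: {bundle.mirna.shape[0]} features x {bundle.mirna.shape[1]} samples")
print(f"mRNA matrix:  {bundle.mrna.shape[0]} features x {bundle.mrna.shape[1]} samples")
print(f"groups: {bundle.metadata['group'].value_counts().to_dict()}")
print(f"planted DE miRNAs: {len(bundle.truth.de_mirna)}")
print(f"planted DE mRNAs (independent of couplings): {len(bundle.truth.de_mrna)}")
print(f"planted repressive pairs: {len(bundle.truth.regulatory_pairs)}")
print(f"binding-site rows (planted + decoys): {len(bundle.sites)}")
detected = bundle.mirna.detected.to_numpy().mean()
print(f"miRNA detection rate: {detected:.3f} (dropout target 0.1)")
# The planted pairs are the edges the downstream network stage should find;
# the decoy sites make the binding-site filter do real work.
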