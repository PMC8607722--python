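"""Generate every pipeline input with planted ground truth and write them
to plain-text files (MTX counts, TSV tables, GMT marker sets, JSON truth)."""
from pathlib import Path

import scburden as sb

cfg = sb.SynthConfig(seed=1)
bundle = sb.generate_all(cfg)

outdir = Path("scratch/example_data")
sb.io.write_bundle(bundle, outdir)

print(f"counts: {bundle.counts.n_cells} cells x {bundle.counts.n_genes} genes")
print(f"variants: {len(bundle.variants)} records")
print(f"exons: {len(bundle.exons)} exon models")
print(f"planted marker genes per type:",
      {t: len(g) for t, g in bundle.truth.marker_catalog.items()})
print(f"planted critical exon flags: {len(bundle.truth.critical_exon_flags)}")
print(f"planted high-pLI genes: {len(bundle.truth.high_pli_genes)}")
print(f"de novo LOF genes: {len(bundle.truth.lof_genes)} "
      f"(of which {len(bundle.truth.enriched_variant_genes)} on the enriched "
      f"astrocyte program)")
print(f"written to {outdir}/")
# Each number reflects a planted signal the downstream stages must recover;
# the JSON truth sidecar is the oracle for that recovery.
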