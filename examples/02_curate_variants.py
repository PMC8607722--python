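"""Summarise a curated variant table and derive the analysis gene sets."""
import scburden as sb

cfg = sb.SynthConfig(seed=1)
truth = sb.GroundTruth(marker_catalog=cfg.marker_catalog)
records = sb.synth.generate_variant_table(cfg, truth)

s = sb.curation.summarize(records)
print(f"{s.n_total} variants; "
      f"{s.inheritance_pct.get('de_novo', 0)}% de novo")
print(f"de novo exonic/splicing: {s.n_de_novo_exonic_splicing} "
      f"({s.de_novo_exonic_splicing_pct}%)")
print(f"of those: LOF {s.category_counts['LOF']} ({s.category_pct['LOF']}%), "
      f"missense {s.category_counts['missense']} "
      f"({s.category_pct['missense']}%)")

lof = sb.curation.lof_gene_set(records)
multi_lof, multi_mis, multi_any = sb.curation.recurrent_gene_sets(records)
print(f"unique de novo LOF genes: {len(lof)}")
print(f"recurrent: {len(multi_lof)} multi-LOF, {len(multi_mis)} "
      f"multi-missense, {len(multi_any)} multi-LOF-or-missense")
# LOF percentages are computed over de novo exonic+splicing records only;
# the LOF gene set is what every downstream enrichment tests against.
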