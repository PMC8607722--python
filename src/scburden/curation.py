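"""Variant-table curation: classification, landscape summary, gene sets.

The variant table arrives pre-annotated (effect class and inheritance are
final calls); this module classifies records into loss-of-function (LOF) /
missense / other, summarises the mutational landscape with the conventional
denominators (inheritance shares over all records; category shares over
de novo exonic + splicing records), and derives the gene sets used by every
downstream enrichment: the unique de novo LOF gene set and the three
recurrent-hit sets (multiple LOF, multiple missense, multiple LOF-or-missense).
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

from .containers import (EXONIC_EFFECTS, GeneSet, LOF_EFFECTS, VariantRecord)

CATEGORIES = ("LOF", "missense", "other")


def classify_variant(v: VariantRecord) -> str:
    """LOF iff nonsense/frameshift/splicing; missense; otherwise other."""
    if v.effect in LOF_EFFECTS:
        return "LOF"
    if v.effect == "missense":
        return "missense"
    return "other"


def _pct(numerator: int, denominator: int) -> float:
    """Percentage at the conventional mixed precision: 2 decimals, but 3 for
    sub-1% shares (e.g. 0.863)."""
    if denominator == 0:
        return 0.0
    x = 100.0 * numerator / denominator
    return round(x, 3) if x < 1.0 else round(x, 2)


@dataclass
class CurationSummary:
    """Counts and percentages describing a curated mutational landscape."""

    n_total: int = 0
    inheritance_counts: dict = field(default_factory=dict)
    inheritance_pct: dict = field(default_factory=dict)
    n_de_novo_exonic_splicing: int = 0
    de_novo_exonic_splicing_pct: float = 0.0
    category_counts: dict = field(default_factory=dict)   # over dn exonic+splicing
    category_pct: dict = field(default_factory=dict)
    effect_counts: dict = field(default_factory=dict)     # dn exonic+splicing effects


def summarize(records: Iterable[VariantRecord]) -> CurationSummary:
    """Summarise the landscape on the stated denominators.

    Inheritance percentages are over all records; category (LOF / missense /
    other) percentages are over de novo exonic + splicing records only.
    """
    records = list(records)
    if not records:
        warnings.warn("empty variant table: all-zero summary")
        return CurationSummary()

    inh = Counter(v.inheritance for v in records)
    n = len(records)

    dn_exonic = [v for v in records
                 if v.inheritance == "de_novo" and v.effect in EXONIC_EFFECTS]
    cat = Counter(classify_variant(v) for v in dn_exonic)
    eff = Counter(v.effect for v in dn_exonic)
    m = len(dn_exonic)

    return CurationSummary(
        n_total=n,
        inheritance_counts=dict(inh),
        inheritance_pct={k: _pct(c, n) for k, c in inh.items()},
        n_de_novo_exonic_splicing=m,
        de_novo_exonic_splicing_pct=_pct(m, n),
        category_counts={c: cat.get(c, 0) for c in CATEGORIES},
        category_pct={c: _pct(cat.get(c, 0), m) for c in CATEGORIES},
        effect_counts=dict(eff),
    )


def lof_gene_set(records: Iterable[VariantRecord]) -> GeneSet:
    """Unique genes with at least one de novo LOF record."""
    genes = {v.gene for v in records
             if v.inheritance == "de_novo" and classify_variant(v) == "LOF"
             and v.gene}
    return GeneSet(name="de_novo_lof_genes", genes=genes,
                   provenance="genes with >= 1 de novo LOF variant")


def recurrent_gene_sets(records: Iterable[VariantRecord]
                        ) -> Tuple[GeneSet, GeneSet, GeneSet]:
    """Genes hit at least twice: (multi-LOF, multi-missense, multi-either).

    The union set counts de novo LOF and missense records jointly, so one LOF
    plus one missense on the same gene qualifies for the third set only.
    """
    lof = Counter()
    mis = Counter()
    for v in records:
        if v.inheritance != "de_novo" or not v.gene:
            continue
        c = classify_variant(v)
        if c == "LOF":
            lof[v.gene] += 1
        elif c == "missense":
            mis[v.gene] += 1
    multi_lof = {g for g, c in lof.items() if c >= 2}
    multi_mis = {g for g, c in mis.items() if c >= 2}
    joint = Counter(lof)
    joint.update(mis)
    multi_any = {g for g, c in joint.items() if c >= 2}
    return (GeneSet("multi_de_novo_lof", multi_lof, ">= 2 de novo LOF"),
            GeneSet("multi_de_novo_missense", multi_mis,
                    ">= 2 de novo missense"),
            GeneSet("multi_de_novo_lof_or_missense", multi_any,
                    ">= 2 de novo LOF or missense jointly"))
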