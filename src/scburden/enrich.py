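"""Gene-set overlap engine: Fisher tests, batch correction, pathway filters.

The core primitive is the 2x2 overlap of two gene sets inside a universe,
scored by the hypergeometric upper tail (one-sided enrichment, the
GeneOverlap convention) with the sample odds ratio as effect size. Batch
enrichment applies Bonferroni jointly over all cluster x gene-set tests;
pathway enrichment adds the size filter (sets below 50 or above 1000 genes
excluded) and the dual cutoff p < 1e-3 and BH FDR < 0.01.
"""
from __future__ import annotations

import warnings
from typing import Dict, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import EnrichmentResult, GeneSet
from .de import adjust


def _table(set_a: set, set_b: set, universe: set) -> tuple:
    n11 = len(set_a & set_b)
    n10 = len(set_a - set_b)
    n01 = len(set_b - set_a)
    n00 = len(universe) - n11 - n10 - n01
    return n11, n10, n01, n00


def odds_ratio(n11: int, n10: int, n01: int, n00: int) -> float:
    """Sample OR; Haldane-Anscombe 0.5 applied only when the denominator
    vanishes (never to the p-value)."""
    if n10 * n01 > 0:
        return (n11 * n00) / (n10 * n01)
    return ((n11 + 0.5) * (n00 + 0.5)) / ((n10 + 0.5) * (n01 + 0.5))


def fisher_overlap(set_a: Union[GeneSet, set], set_b: Union[GeneSet, set],
                   universe: Iterable[str], two_sided: bool = False,
                   name_a: str = "set_a", name_b: str = "set_b"
                   ) -> EnrichmentResult:
    """Hypergeometric overlap test of two sets inside a universe.

    One-sided enrichment p = P(overlap >= observed) under the hypergeometric
    null; ``two_sided=True`` uses the two-sided Fisher exact p instead.
    """
    if isinstance(set_a, GeneSet):
        name_a, set_a = set_a.name, set_a.genes
    if isinstance(set_b, GeneSet):
        name_b, set_b = set_b.name, set_b.genes
    universe = set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not set_a or not set_b:
        raise ValueError("empty gene set")
    set_a, set_b = set(set_a) & universe, set(set_b) & universe
    if not set_a.issubset(universe) or not set_b.issubset(universe):
        raise ValueError("sets must be subsets of the universe")
    n11, n10, n01, n00 = _table(set_a, set_b, universe)
    if two_sided:
        p = float(st.fisher_exact([[n11, n10], [n01, n00]],
                                  alternative="two-sided")[1])
    else:
        p = float(st.hypergeom.sf(n11 - 1, len(universe), len(set_b),
                                  len(set_a)))
    return EnrichmentResult(
        set_a_name=name_a, set_b_name=name_b, universe_size=len(universe),
        a_size=len(set_a), b_size=len(set_b), overlap=n11,
        odds_ratio=odds_ratio(n11, n10, n01, n00), p=p, p_adj=p,
        method="fisher")


def batch_enrich(cluster_deg_map: Mapping, gene_sets: Sequence,
                 universe: Iterable[str], correction: str = "bonferroni"
                 ) -> pd.DataFrame:
    """All cluster x gene-set overlaps, corrected jointly.

    ``gene_sets`` is a sequence of :class:`GeneSet` (names must be unique)
    or a mapping name -> genes. Returns one row per test with the corrected
    p-value over the whole batch.
    """
    if isinstance(gene_sets, Mapping):
        gene_sets = [GeneSet(k, set(v)) for k, v in gene_sets.items()]
    names = [gs.name for gs in gene_sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene-set names in batch")
    universe = set(universe)
    rows = []
    for cname, degs in cluster_deg_map.items():
        for gs in gene_sets:
            r = fisher_overlap(set(degs), gs.genes, universe,
                               name_a=str(cname), name_b=gs.name)
            rows.append(r)
    df = pd.DataFrame([{
        "cluster": r.set_a_name, "gene_set": r.set_b_name,
        "universe_size": r.universe_size, "a_size": r.a_size,
        "b_size": r.b_size, "overlap": r.overlap,
        "odds_ratio": r.odds_ratio, "p": r.p} for r in rows])
    df["p_adj"] = adjust(df["p"].to_numpy(), method=correction)
    return df


def pathway_enrichment(query_set: Union[GeneSet, set],
                       collection: Sequence[GeneSet],
                       universe: Iterable[str],
                       min_size: int = 50, max_size: int = 1000,
                       p_cut: float = 1e-3, fdr_cut: float = 0.01
                       ) -> pd.DataFrame:
    """Pathway overlap with the size filter and dual significance cutoff.

    Sets with fewer than ``min_size`` or more than ``max_size`` genes are
    excluded (bounds inclusive: 50 and 1000 are retained); Fisher p per
    retained set; BH FDR across retained sets; a pathway is significant iff
    p < p_cut and FDR < fdr_cut.
    """
    if isinstance(query_set, GeneSet):
        query = query_set.genes
    else:
        query = set(query_set)
    kept = [gs for gs in collection if min_size <= len(gs.genes) <= max_size]
    if not kept:
        warnings.warn("no pathway sets within the size bounds")
        return pd.DataFrame(columns=["pathway", "size", "overlap",
                                     "odds_ratio", "p", "fdr", "significant"])
    universe = set(universe)
    rows = []
    for gs in kept:
        r = fisher_overlap(query, gs.genes, universe,
                           name_a="query", name_b=gs.name)
        rows.append({"pathway": gs.name, "size": len(gs.genes),
                     "overlap": r.overlap, "odds_ratio": r.odds_ratio,
                     "p": r.p})
    df = pd.DataFrame(rows)
    df["fdr"] = adjust(df["p"].to_numpy(), method="bh")
    df["significant"] = (df["p"] < p_cut) & (df["fdr"] < fdr_cut)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|intersection| / |union|; 0 for two empty sets by convention."""
    a, b = set(set_a), set(set_b)
    union = a | b
    return len(a & b) / len(union) if union else 0.0
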