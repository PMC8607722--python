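"""Evolutionary-constraint scoring: critical exons and pLI enrichment.

A critical exon (CE) is an exon that is simultaneously highly expressed in
brain at a developmental stage and depleted of non-synonymous mutations
relative to its length. Operationally this package flags an exon at a stage
iff its stage expression reaches the upper expression quantile (default
0.75) and its per-bp mutation burden is at or below the lower burden
quantile (default 0.25), with per-stage thresholds; the quadrant rule with
exposed quantile parameters is this package's interpretive choice and both
knobs are configurable. Gene-level CE sets (genes with >= 1 critical exon at
a stage) feed a two-sample proportion test against cluster DEG lists; pLI
(probability of loss-of-function intolerance, high >= 0.9) feeds Fisher's
exact test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import (EnrichmentResult, ExonRecord, GeneSet, STAGES)
from .enrich import fisher_overlap, odds_ratio

logger = logging.getLogger(__name__)


def exon_burden(e: ExonRecord) -> float:
    """Non-synonymous mutations per base pair."""
    if e.length_bp <= 0:
        raise ValueError("exon length must be positive")
    return e.nonsyn_count / e.length_bp


@dataclass
class CriticalExonMatrix:
    """Boolean flags over (gene, exon_index, stage), with the quantile
    parameters that produced them."""

    flags: Dict[Tuple[str, int, str], bool] = field(default_factory=dict)
    q_e: float = 0.75
    q_b: float = 0.25

    def stages(self) -> set:
        return {s for (_, _, s) in self.flags}

    def flagged(self, stage: str) -> set:
        return {(g, i) for (g, i, s), v in self.flags.items()
                if s == stage and v}


def critical_exons(exons: Sequence[ExonRecord], stage: str,
                   q_e: float = 0.75, q_b: float = 0.25,
                   matrix: CriticalExonMatrix | None = None
                   ) -> CriticalExonMatrix:
    """Flag one stage slice: expression >= quantile q_e AND burden <=
    quantile q_b (quantiles over all exons at that stage)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if len(exons) < 20:
        raise ValueError("need >= 20 exons for meaningful quantiles")
    expr = np.array([e.expr[stage] for e in exons], dtype=float)
    if np.allclose(expr, expr[0]):
        raise ValueError(f"all-equal expressions at stage {stage}: "
                         "degenerate quantiles")
    burden = np.array([exon_burden(e) for e in exons])
    e_thr = np.quantile(expr, q_e)
    b_thr = np.quantile(burden, q_b)
    if matrix is None:
        matrix = CriticalExonMatrix(q_e=q_e, q_b=q_b)
    for e, x, b in zip(exons, expr, burden):
        matrix.flags[(e.gene, e.exon_index, stage)] = \
            bool(x >= e_thr and b <= b_thr)
    return matrix


def critical_exon_matrix(exons: Sequence[ExonRecord],
                         q_e: float = 0.75, q_b: float = 0.25
                         ) -> CriticalExonMatrix:
    """All three stage slices with per-stage quantile thresholds."""
    matrix = CriticalExonMatrix(q_e=q_e, q_b=q_b)
    for stage in STAGES:
        critical_exons(exons, stage, q_e=q_e, q_b=q_b, matrix=matrix)
    return matrix


def ce_gene_set(matrix: CriticalExonMatrix, stage: str) -> GeneSet:
    """Genes with at least one critical exon at the given stage."""
    genes = {g for (g, _, s), v in matrix.flags.items() if s == stage and v}
    return GeneSet(name=f"critical_exon_genes_{stage}", genes=genes,
                   provenance=f"CE quadrant rule q_e={matrix.q_e}, "
                              f"q_b={matrix.q_b}")


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> Tuple[float, float]:
    """Two-sample proportion test, two-sided, no continuity correction.

    Returns (z_squared, p). z**2 equals the Pearson chi-square of the 2x2
    table exactly.
    """
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group in proportion test")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom == 0:
        return 0.0, 1.0
    z2 = (p1 - p2) ** 2 / denom
    return float(z2), float(st.chi2.sf(z2, 1))


def ce_enrichment(cluster_genes: Iterable[str], ce_genes: Iterable[str],
                  universe: Iterable[str]) -> EnrichmentResult:
    """Is the CE fraction among cluster genes above background?

    Compares the CE fraction inside the cluster DEG list against the CE
    fraction of the remaining universe (two-sample proportion test); the
    odds ratio is read off the induced 2x2 table.
    """
    universe = set(universe)
    cluster = set(cluster_genes) & universe
    ce = set(ce_genes) & universe
    if not cluster:
        raise ValueError("empty cluster gene set")
    rest = universe - cluster
    k1, n1 = len(cluster & ce), len(cluster)
    k2, n2 = len(rest & ce), len(rest)
    z2, p = proportion_test(k1, n1, k2, n2)
    orr = odds_ratio(k1, n1 - k1, k2, n2 - k2)
    return EnrichmentResult(
        set_a_name="cluster", set_b_name="critical_exon_genes",
        universe_size=len(universe), a_size=n1, b_size=len(ce),
        overlap=k1, odds_ratio=orr, p=p, p_adj=p, method="proportion")


def pli_enrichment(cluster_genes: Iterable[str], pli_table: pd.DataFrame,
                   universe: Iterable[str], cutoff: float = 0.9
                   ) -> EnrichmentResult:
    """Fisher's exact overlap of cluster genes with high-pLI genes.

    Genes missing from the pLI table are excluded from the universe (the
    number excluded is logged).
    """
    pli = pli_table.set_index("gene")["pli"] \
        if "gene" in pli_table.columns else pli_table.squeeze()
    universe = set(universe)
    known = universe & set(pli.index)
    dropped = len(universe) - len(known)
    if dropped:
        logger.info("pli_enrichment: %d universe genes missing from the "
                    "pLI table, excluded", dropped)
    high = {g for g in known if pli[g] >= cutoff}
    cluster = set(cluster_genes) & known
    if not cluster or not high:
        raise ValueError("empty cluster or high-pLI set after filtering")
    res = fisher_overlap(cluster, high, known, name_a="cluster",
                         name_b=f"pli_ge_{cutoff}")
    return res
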