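"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes is generated here: a negative-binomial
cell x gene count matrix with planted cell types and marker genes, a curated
variant table with a planted loss-of-function enrichment in one cell-type
program, exon models with planted critical exons, gene-level pLI scores,
a gene x (region, period) developmental expression grid with a planted
prenatal bias, and a sorted-cell-type mean-expression reference.

Distributional choices are artifact choices that make the planted signal
analytically checkable; they are not claims about any real atlas. Each
component draws from its own random substream of the single config seed, so
adding a component never perturbs the draws of another.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (CellByGeneCounts, ExonRecord, SortedCellExpr,
                         SORTED_CELL_TYPES, SpatioTemporalExpr, STAGES,
                         VariantRecord, EFFECTS, INHERITANCE, LOF_EFFECTS)

#: 16 region labels of the developmental expression grid (standard
#: developing-human-brain region abbreviations).
DEFAULT_REGIONS = ("AMY", "CBC", "V1C", "STC", "IPC", "A1C", "S1C", "M1C",
                   "STR", "DFC", "MFC", "VFC", "OFC", "MD", "ITC", "HIP")

DEFAULT_PERIODS = ("prenatal", "early_childhood", "adult")

# substream ids: one per generated component
_STREAMS = {"counts": 0, "variants": 1, "exons": 2, "pli": 3,
            "spatiotemporal": 4, "sorted": 5}


def _default_variant_counts() -> dict:
    # a 1/10-scale mutational landscape: mostly de novo noncoding, a de novo
    # exonic/splicing core dominated by missense, and a small LOF slice
    return {
        ("nonsense", "de_novo"): 47,
        ("frameshift", "de_novo"): 41,
        ("splicing", "de_novo"): 20,
        ("missense", "de_novo"): 665,
        ("synonymous", "de_novo"): 283,
        ("noncoding", "de_novo"): 1000,
        ("missense", "inherited"): 50,
        ("noncoding", "unknown"): 100,
    }


@dataclass
class SynthConfig:
    """All simulation knobs, with the study conditions as defaults."""

    seed: int = 0
    n_genes: int = 2000
    cell_type_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"neurons": 200, "astrocytes": 150,
                                 "oligodendrocytes": 150})
    n_markers_per_type: int = 50
    marker_log2_effect: float = 2.0
    baseline_dispersion: float = 0.5  # NB: var = mu + disp * mu^2
    library_size_range: Tuple[int, int] = (5000, 20000)
    frac_critical_exons: float = 0.1
    frac_high_pli: float = 0.1
    variant_category_counts: Mapping[tuple, int] = field(
        default_factory=_default_variant_counts)
    enriched_program: str = "astrocytes"
    enrichment_multiplier: float = 20.0
    regions: tuple = DEFAULT_REGIONS
    periods: tuple = DEFAULT_PERIODS
    prenatal_bias_log2: float = 2.0
    bias_regions: tuple = ("DFC", "V1C")
    n_prenatal_biased: int = 100
    exons_per_gene_range: Tuple[int, int] = (1, 20)
    exon_length_range: Tuple[int, int] = (1000, 3000)
    exon_mut_rate_per_bp: float = 0.02
    critical_burden_factor: float = 0.25  # planted-CE Poisson rate multiplier
    sorted_restriction_ratio: float = 8.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, size in self.cell_type_sizes.items():
            if size <= 0:
                raise ValueError(
                    f"cell type {name!r} has non-positive size {size}")
        if self.n_genes <= 0 or self.n_markers_per_type <= 0:
            raise ValueError("n_genes and n_markers_per_type must be positive")
        n_types = len(self.cell_type_sizes)
        if n_types * self.n_markers_per_type > self.n_genes:
            raise ValueError("marker sets (disjoint) exceed the gene universe")
        for frac in (self.frac_critical_exons, self.frac_high_pli):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if len(self.periods) != 3:
            raise ValueError("periods must list exactly 3 developmental periods")
        if self.baseline_dispersion <= 0:
            raise ValueError("baseline_dispersion must be positive")
        if self.enrichment_multiplier < 1:
            raise ValueError("enrichment_multiplier must be >= 1")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid library_size_range")
        for cat in self.variant_category_counts:
            effect, inh = cat
            if effect not in EFFECTS or inh not in INHERITANCE:
                raise ValueError(f"unknown variant category {cat!r}")

    def rng(self, component: str) -> np.random.Generator:
        """Independent substream for one generated component."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(_STREAMS[component],)))

    @property
    def gene_ids(self) -> np.ndarray:
        return np.array([f"G{i:05d}" for i in range(self.n_genes)],
                        dtype=object)

    @property
    def marker_catalog(self) -> dict:
        """Disjoint planted marker sets: contiguous gene blocks per type."""
        genes = self.gene_ids
        catalog, start = {}, 0
        for ct in self.cell_type_sizes:
            catalog[ct] = set(genes[start:start + self.n_markers_per_type])
            start += self.n_markers_per_type
        return catalog


@dataclass
class GroundTruth:
    """Planted truth: the oracle every downstream stage is scored against."""

    cell_labels: dict = field(default_factory=dict)          # cell -> type
    marker_catalog: dict = field(default_factory=dict)       # type -> genes
    critical_exon_flags: set = field(default_factory=set)    # (gene, idx, stage)
    high_pli_genes: set = field(default_factory=set)
    enriched_variant_genes: set = field(default_factory=set)
    prenatal_biased_genes: set = field(default_factory=set)
    lof_genes: set = field(default_factory=set)              # all de novo LOF genes

    def is_critical(self, gene: str, exon_index: int, stage: str) -> bool:
        return (gene, exon_index, stage) in self.critical_exon_flags


def expected_marker_means(config: SynthConfig, rel_expr: np.ndarray,
                          library_size: float) -> np.ndarray:
    """Closed-form NB mean of each gene at a given library size (home type
    of a marker multiplies its relative rate by 2**marker_log2_effect)."""
    return library_size * rel_expr / rel_expr.sum()


def generate_counts(config: SynthConfig) -> Tuple[CellByGeneCounts, GroundTruth]:
    """Sample the cell x gene count matrix and record planted truth.

    Counts are negative binomial with gene-level baseline rates drawn
    log-normal and per-cell library-size scaling; a marker gene's rate in its
    home type is shifted up by ``marker_log2_effect`` on the log2 scale. The
    per-cell mitochondrial fraction is correlated with library size so the
    regression step downstream has signal to remove.
    """
    config.validate()
    rng = config.rng("counts")
    genes = config.gene_ids
    catalog = config.marker_catalog

    rel = np.exp(rng.normal(0.0, 1.0, size=config.n_genes))  # relative rates
    # markers are, by definition, expressed genes: draw their baselines from
    # a moderately-expressed stratum so none sits in the silent tail
    all_marker_idx = np.array(sorted(
        i for i, g in enumerate(genes)
        if any(g in catalog[ct] for ct in catalog)))
    rel[all_marker_idx] = np.exp(
        rng.normal(0.5, 0.5, size=all_marker_idx.size))
    rel_sum = rel.sum()

    cell_types, cell_ids = [], []
    for ct, size in config.cell_type_sizes.items():
        cell_types += [ct] * size
        cell_ids += [f"{ct[:4].upper()}_{i:04d}" for i in range(size)]
    n_cells = len(cell_types)

    lo, hi = config.library_size_range
    libs = rng.integers(lo, hi + 1, size=n_cells)

    marker_cols = {ct: np.array(sorted(config.gene_ids.tolist().index(g)
                                       for g in catalog[ct]))
                   for ct in catalog}
    effect = 2.0 ** config.marker_log2_effect

    theta = 1.0 / config.baseline_dispersion  # NB size parameter
    counts = np.empty((n_cells, config.n_genes), dtype=np.int64)
    for i, (ct, lib) in enumerate(zip(cell_types, libs)):
        rate = rel.copy()
        rate[marker_cols[ct]] *= effect
        mu = lib * rate / rel_sum
        p = theta / (theta + mu)
        counts[i] = rng.negative_binomial(theta, p)

    lib_z = (libs - libs.mean()) / max(libs.std(), 1e-12)
    pmito = np.clip(0.05 + 0.02 * lib_z + rng.normal(0, 0.01, n_cells),
                    0.005, 0.25)
    meta = pd.DataFrame(
        {"donor": rng.choice(["D1", "D2"], size=n_cells),
         "region": "ACC",
         "percent_mito": pmito,
         "library_size": libs},
        index=pd.Index(cell_ids, name="cell_id"))

    truth = GroundTruth(cell_labels=dict(zip(cell_ids, cell_types)),
                        marker_catalog=catalog)
    return CellByGeneCounts(sp.csr_matrix(counts), meta, genes), truth


def lof_sampling_weights(config: SynthConfig) -> np.ndarray:
    """Renormalised gene-sampling weights for de novo LOF records."""
    w = np.ones(config.n_genes)
    program = config.marker_catalog.get(config.enriched_program, set())
    idx = [i for i, g in enumerate(config.gene_ids) if g in program]
    w[idx] *= config.enrichment_multiplier
    return w / w.sum()


def generate_variant_table(config: SynthConfig,
                           truth: GroundTruth) -> list:
    """Sample exactly the requested number of records per category.

    Genes for de novo LOF records are drawn with probability multiplied by
    ``enrichment_multiplier`` on the enriched program's marker genes; the
    planted enriched genes are recorded in ``truth``.
    """
    rng = config.rng("variants")
    genes = config.gene_ids
    uniform = np.full(config.n_genes, 1.0 / config.n_genes)
    lof_w = lof_sampling_weights(config)
    program = config.marker_catalog.get(config.enriched_program, set())

    records = []
    i = 0
    for (effect, inh), count in config.variant_category_counts.items():
        if effect not in EFFECTS or inh not in INHERITANCE:
            raise ValueError(f"unknown variant category {(effect, inh)!r}")
        weights = lof_w if (effect in LOF_EFFECTS and inh == "de_novo") \
            else uniform
        gidx = rng.choice(config.n_genes, size=count, p=weights)
        for j in gidx:
            gene = "" if effect == "noncoding" else str(genes[j])
            records.append(VariantRecord(
                variant_id=f"v{i:07d}", gene=gene, effect=effect,
                inheritance=inh, case_id=f"case{rng.integers(0, 10000):05d}"))
            i += 1
            if effect in LOF_EFFECTS and inh == "de_novo":
                truth.lof_genes.add(gene)
                if gene in program:
                    truth.enriched_variant_genes.add(gene)
    return records


def generate_exon_models(config: SynthConfig, truth: GroundTruth) -> list:
    """Exon models with planted critical exons.

    A planted critical exon draws its stage expression from a high log-normal
    stratum (well inside the top quartile) and its mutation count from a
    Poisson with rate ``critical_burden_factor`` times baseline per bp, which
    makes the high-expression/low-burden quadrant identifiable.
    """
    rng = config.rng("exons")
    lo_n, hi_n = config.exons_per_gene_range
    lo_l, hi_l = config.exon_length_range

    n_exons_per_gene = rng.integers(lo_n, hi_n + 1, size=config.n_genes)
    keys = [(str(g), int(e + 1)) for g, n in zip(config.gene_ids,
                                                 n_exons_per_gene)
            for e in range(n)]
    total = len(keys)
    n_crit = int(round(config.frac_critical_exons * total))
    crit_pos = set(rng.choice(total, size=n_crit, replace=False).tolist())

    rate = config.exon_mut_rate_per_bp
    records = []
    for pos, (gene, idx) in enumerate(keys):
        length = int(rng.integers(lo_l, hi_l + 1))
        if pos in crit_pos:
            count = int(rng.poisson(rate * config.critical_burden_factor
                                    * length))
            expr = {s: float(np.exp(rng.normal(2.5, 0.3))) for s in STAGES}
            for s in STAGES:
                truth.critical_exon_flags.add((gene, idx, s))
        else:
            count = int(rng.poisson(rate * length))
            expr = {s: float(np.exp(rng.normal(0.0, 1.0))) for s in STAGES}
        records.append(ExonRecord(gene=gene, exon_index=idx, length_bp=length,
                                  nonsyn_count=count, expr=expr))
    return records


def generate_pli(config: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Gene-level pLI table with a planted high-constraint stratum.

    Exactly ``round(frac_high_pli * n_genes)`` genes draw pLI from
    U(0.95, 1), preferentially the enriched program's markers; the rest draw
    from U(0, 0.5). The strata are disjoint around the 0.9 cutoff, so the
    planted set is exactly recoverable.
    """
    rng = config.rng("pli")
    genes = config.gene_ids
    n_high = int(round(config.frac_high_pli * config.n_genes))
    program = sorted(config.marker_catalog.get(config.enriched_program, set()))
    high = list(program[:n_high])
    others = [g for g in genes if g not in set(high)]
    if len(high) < n_high:
        extra = rng.choice(len(others), size=n_high - len(high), replace=False)
        high += [others[int(i)] for i in extra]
    high_set = set(high)

    pli = pd.Series(index=pd.Index(genes, name="gene"), dtype=float)
    is_high = np.array([g in high_set for g in genes])
    pli[is_high] = rng.uniform(0.95, 1.0, size=int(is_high.sum()))
    pli[~is_high] = rng.uniform(0.0, 0.5, size=int((~is_high).sum()))
    truth.high_pli_genes = high_set
    return pli.rename("pli").reset_index()


def generate_spatiotemporal(config: SynthConfig,
                            truth: GroundTruth) -> SpatioTemporalExpr:
    """Gene x (region, period) grid with a planted prenatal bias.

    Biased genes (by default the de novo LOF genes recorded in truth, else a
    random draw of ``n_prenatal_biased`` genes) are shifted up by
    ``prenatal_bias_log2`` in the prenatal period of the designated regions.
    """
    if len(config.regions) != 16:
        warnings.warn(f"regions list has length {len(config.regions)}, "
                      "expected 16; proceeding")
    rng = config.rng("spatiotemporal")
    genes = config.gene_ids
    cols = pd.MultiIndex.from_product([config.regions, config.periods],
                                      names=["region", "period"])
    base = np.exp(rng.normal(0.0, 1.0, size=config.n_genes))
    noise = np.exp(rng.normal(0.0, 0.3, size=(config.n_genes, len(cols))))
    values = base[:, None] * noise

    if truth.lof_genes:
        biased = set(g for g in truth.lof_genes if g)
    else:
        pick = rng.choice(config.n_genes,
                          size=min(config.n_prenatal_biased, config.n_genes),
                          replace=False)
        biased = set(str(genes[int(i)]) for i in pick)
    truth.prenatal_biased_genes = biased

    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=cols)
    prenatal = config.periods[0]
    bias = 2.0 ** config.prenatal_bias_log2
    gmask = df.index.isin(biased)
    for region in config.bias_regions:
        if region in config.regions:
            df.loc[gmask, (region, prenatal)] *= bias
    return SpatioTemporalExpr(values=df, regions=tuple(config.regions),
                              periods=tuple(config.periods))


def generate_sorted_cell_reference(config: SynthConfig,
                                   truth: GroundTruth) -> SortedCellExpr:
    """Gene x sorted-cell-type mean expression reference.

    Planted restricted genes (the enriched program's markers) have their
    column for that cell type multiplied by ``sorted_restriction_ratio``, so
    their fold change versus neurons is recoverable. Detection fractions are
    high for 90% of genes and sub-threshold for the remaining 10% to exercise
    the detection filter.
    """
    rng = config.rng("sorted")
    genes = config.gene_ids
    base = np.exp(rng.normal(1.0, 0.5, size=config.n_genes))
    noise = np.exp(rng.normal(0.0, 0.3,
                              size=(config.n_genes, len(SORTED_CELL_TYPES))))
    values = base[:, None] * noise
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=list(SORTED_CELL_TYPES))

    program = config.marker_catalog.get(config.enriched_program, set())
    if config.enriched_program in SORTED_CELL_TYPES and program:
        gmask = df.index.isin(program)
        df.loc[gmask, config.enriched_program] *= config.sorted_restriction_ratio

    low = rng.random(config.n_genes) < 0.1
    detection = np.where(low, rng.uniform(0.0, 0.7, config.n_genes),
                         rng.uniform(0.8, 1.0, config.n_genes))
    det = pd.Series(detection, index=df.index, name="detection")
    return SortedCellExpr(values=df, species="synthetic", detection=det)


@dataclass
class SynthBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SynthConfig
    counts: CellByGeneCounts
    variants: list
    exons: list
    pli: pd.DataFrame
    spatiotemporal: SpatioTemporalExpr
    sorted_reference: SortedCellExpr
    truth: GroundTruth


def generate_all(config: SynthConfig) -> SynthBundle:
    """Generate every input in dependency order under one seed."""
    counts, truth = generate_counts(config)
    variants = generate_variant_table(config, truth)
    exons = generate_exon_models(config, truth)
    pli = generate_pli(config, truth)
    st = generate_spatiotemporal(config, truth)
    ref = generate_sorted_cell_reference(config, truth)
    return SynthBundle(config=config, counts=counts, variants=variants,
                       exons=exons, pli=pli, spatiotemporal=st,
                       sorted_reference=ref, truth=truth)
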