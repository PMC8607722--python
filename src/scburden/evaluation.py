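"""End-to-end recovery evaluation against planted ground truth.

One replicate runs the whole pipeline on a freshly generated dataset and
scores every stage against the truth the generator planted: clustering
(adjusted Rand index), consensus DE (marker sensitivity and truth-FDR),
critical-exon flags (sensitivity/specificity), the planted LOF-enriched
program (Bonferroni-significant cluster x LOF-gene-set overlap), cluster
annotation (the planted astrocyte program called "astrocytes"), and the
planted prenatal expression bias (grid cell with maximal odds ratio).
Null-calibration helpers simulate effect-free data and measure type-I error.
"""
from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import annotate, constraint, curation, de, enrich, scpipe
from . import spatiotemporal as stmod
from .containers import STAGES
from .synth import SynthConfig, generate_all


def replicate_metrics(seed: int, config: Optional[SynthConfig] = None,
                      resolution: float = 0.5) -> Dict[str, float]:
    """Run the full pipeline once and score recovery of every planted signal.

    The clustering resolution defaults to 0.5, matched to the granularity of
    the planted structure (a few broad cell types) the same way resolution
    is chosen per dataset in real analyses; higher resolutions legitimately
    split broad types into subtypes, which the ARI against broad planted
    labels would penalise. Returns a flat dict of metrics; boolean outcomes
    are encoded 0/1 so rates can be averaged over seeds.
    """
    if config is None:
        config = SynthConfig(seed=seed)
    bundle = generate_all(config)
    truth = bundle.truth

    labeling, norm, _ = scpipe.run_clustering(
        bundle.counts, resolution=resolution, seed=seed)
    cell_types = np.array([truth.cell_labels[c]
                           for c in bundle.counts.cell_ids])
    ari = adjusted_rand_score(cell_types, labeling.labels)

    # majority planted type per recovered cluster
    labels = np.asarray(labeling.labels)
    majority = {}
    for c in labeling.cluster_ids:
        vals, counts = np.unique(cell_types[labels == c], return_counts=True)
        majority[c] = vals[counts.argmax()]

    cons = de.run_consensus_de(norm, labeling)
    sens, fdr = [], []
    for c, tbl in cons.tables.items():
        markers = truth.marker_catalog[majority[c]]
        called = set(tbl.loc[tbl["log2_fc"] > 0, "gene"])
        sens.append(len(called & markers) / len(markers))
        if called:
            fdr.append(len(called - markers) / len(called))

    universe = list(bundle.counts.gene_ids)
    lof = curation.lof_gene_set(bundle.variants)
    batch = enrich.batch_enrich(cons.gene_sets(), [lof], universe)
    program_clusters = {str(c) for c, t in majority.items()
                        if t == config.enriched_program}
    sig_clusters = set(batch.loc[batch["p_adj"] < 0.05, "cluster"])
    lof_detected = bool(program_clusters) and \
        program_clusters <= sig_clusters

    comp = annotate.top_deg_composition(cons, truth.marker_catalog)
    mexpr = annotate.mean_marker_expression(norm, labeling,
                                            truth.marker_catalog)
    calls = annotate.assign_all(comp, mexpr)
    astro_called = any(
        calls[c].call == config.enriched_program
        for c in calls if majority[c] == config.enriched_program)

    matrix = constraint.critical_exon_matrix(bundle.exons)
    all_exons = {(e.gene, e.exon_index) for e in bundle.exons}
    ce_sens, ce_spec = [], []
    for stage in STAGES:
        flagged = matrix.flagged(stage)
        planted = {(g, i) for (g, i, s) in truth.critical_exon_flags
                   if s == stage}
        ce_sens.append(len(flagged & planted) / max(len(planted), 1))
        negatives = all_exons - planted
        ce_spec.append(1 - len(flagged - planted) / max(len(negatives), 1))

    assoc = stmod.stage_region_association(universe, bundle.spatiotemporal,
                                           truth.prenatal_biased_genes)
    prenatal_hit = stmod.argmax_period(assoc) == config.periods[0]

    return {
        "ari": float(ari),
        "de_sensitivity": float(np.mean(sens)),
        "de_truth_fdr": float(np.mean(fdr)) if fdr else 0.0,
        "lof_enrichment_detected": float(lof_detected),
        "astrocyte_called": float(astro_called),
        "ce_sensitivity": float(np.mean(ce_sens)),
        "ce_specificity": float(np.mean(ce_spec)),
        "prenatal_argmax": float(prenatal_hit),
        "n_cells": int(bundle.counts.n_cells),
        "n_genes": int(bundle.counts.n_genes),
    }


def null_type_one_error(seed: int, n_genes: int = 1000,
                        n_per_group: int = 200, alpha: float = 0.05,
                        dispersion: float = 0.5) -> Dict[str, float]:
    """Type-I error of each DE test on effect-free NB expression.

    Simulates ``n_genes`` null genes (both groups from the same negative
    binomial, log2-CPM-like transformed) and returns the rejection rate of
    each test at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    theta = 1.0 / dispersion
    mu = np.exp(rng.normal(1.0, 1.0, size=n_genes))
    p = theta / (theta + mu)
    A = rng.negative_binomial(theta, p, size=(n_per_group, n_genes))
    B = rng.negative_binomial(theta, p, size=(n_per_group, n_genes))
    A = np.log2(1.0 + A.astype(float))
    B = np.log2(1.0 + B.astype(float))
    out = {}
    for name in de.TEST_NAMES:
        pvals = de._BATCH[name](A, B)
        out[name] = float(np.mean(pvals < alpha))
    return out


def housekeeping_negative_control(deg_map: Dict, universe, markers: set,
                                  seed: int = 0, runs: int = 200,
                                  set_size: int = 60) -> int:
    """Number of Bonferroni-significant hits for random non-marker
    (housekeeping-like) gene sets over ``runs`` draws; expected 0."""
    from .containers import GeneSet
    rng = np.random.default_rng(seed)
    non_marker = [g for g in universe if g not in markers]
    n_sig = 0
    for _ in range(runs):
        hk = GeneSet("housekeeping",
                     set(rng.choice(non_marker, set_size, replace=False)))
        df = enrich.batch_enrich(deg_map, [hk], universe)
        n_sig += int((df["p_adj"] < 0.05).sum())
    return n_sig
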