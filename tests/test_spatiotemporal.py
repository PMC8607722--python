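"""Developmental association grid and sorted-cell replication."""
import numpy as np
import pandas as pd
import pytest

import scburden as sb
from scburden.containers import SortedCellExpr, SORTED_CELL_TYPES
from scburden.spatiotemporal import (argmax_period, association_grid,
                                     compare_sets, detection_filter,
                                     fold_change_vs_neurons,
                                     stage_region_association)
from scburden.synth import generate_spatiotemporal

from conftest import small_config


# ------------------------------------------------------------ association

def test_grid_has_exactly_48_cells(bundle):
    res = stage_region_association(list(bundle.counts.gene_ids),
                                   bundle.spatiotemporal,
                                   bundle.truth.prenatal_biased_genes)
    assert len(res) == 48
    df = association_grid(res)
    assert set(df["period"]) == set(bundle.config.periods)


def test_null_association_or_near_one():
    """Variant genes uncorrelated with expression: the median OR over grid
    cells sits in [0.8, 1.25]."""
    cfg = small_config(seed=31, prenatal_bias_log2=0.0)
    truth = sb.GroundTruth()
    st_expr = generate_spatiotemporal(cfg, truth)
    rng = np.random.default_rng(1)
    genes = list(st_expr.genes)
    variant = set(rng.choice(genes, 100, replace=False))
    res = stage_region_association(genes, st_expr, variant)
    ors = [r.odds_ratio for r in res.values()
           if not r.degenerate and np.isfinite(r.odds_ratio)]
    assert 0.8 <= np.median(ors) <= 1.25


def test_planted_prenatal_bias_recovered(bundle):
    res = stage_region_association(list(bundle.counts.gene_ids),
                                   bundle.spatiotemporal,
                                   bundle.truth.prenatal_biased_genes)
    assert argmax_period(res) == "prenatal"


def test_null_grid_false_positive_rate_bounded():
    """With zero bias everywhere, < 10% of grid cells reach p < 0.05 over
    repeated null simulations."""
    flagged = total = 0
    for seed in range(5):
        cfg = small_config(seed=100 + seed, prenatal_bias_log2=0.0)
        truth = sb.GroundTruth()
        st_expr = generate_spatiotemporal(cfg, truth)
        rng = np.random.default_rng(seed)
        genes = list(st_expr.genes)
        variant = set(rng.choice(genes, 100, replace=False))
        res = stage_region_association(genes, st_expr, variant)
        for r in res.values():
            if not r.degenerate:
                total += 1
                flagged += r.p < 0.05
    assert flagged / total <= 0.1


def test_degenerate_grid_cell_flagged():
    genes = [f"g{i}" for i in range(30)]
    cols = pd.MultiIndex.from_product(
        [("R1", "R2"), ("prenatal", "early_childhood", "adult")],
        names=["region", "period"])
    values = pd.DataFrame(np.ones((30, 6)),
                          index=pd.Index(genes, name="gene"), columns=cols)
    values[("R2", "adult")] = np.arange(30, dtype=float)
    st_expr = sb.SpatioTemporalExpr(values=values, regions=("R1", "R2"),
                                    periods=("prenatal", "early_childhood",
                                             "adult"))
    res = stage_region_association(genes, st_expr, set(genes[:5]))
    assert res[("R1", "prenatal")].degenerate
    assert not res[("R2", "adult")].degenerate


def test_missing_genes_rejected(bundle):
    with pytest.raises(ValueError, match="absent"):
        stage_region_association(["NOPE"], bundle.spatiotemporal, set())


def test_association_invariant_to_gene_relabelling(bundle):
    genes = list(bundle.counts.gene_ids)
    variant = bundle.truth.prenatal_biased_genes
    res1 = stage_region_association(genes, bundle.spatiotemporal, variant)
    mapping = {g: f"X_{g}" for g in genes}
    st2 = sb.SpatioTemporalExpr(
        values=bundle.spatiotemporal.values.rename(index=mapping),
        regions=bundle.spatiotemporal.regions,
        periods=bundle.spatiotemporal.periods)
    res2 = stage_region_association([mapping[g] for g in genes], st2,
                                    {mapping[g] for g in variant})
    for key in res1:
        assert res1[key].p == pytest.approx(res2[key].p, rel=1e-12)


# ------------------------------------------------------------- detection

def test_detection_filter_threshold():
    genes = ["a", "b", "c", "d", "e"]
    values = pd.DataFrame(np.ones((5, 5)), index=genes,
                          columns=list(SORTED_CELL_TYPES))
    det = pd.Series([0.8, 0.75, 0.74, 1.0, 0.2], index=genes)
    ref = SortedCellExpr(values=values, detection=det)
    kept = detection_filter(ref, min_fraction=0.75)
    assert list(kept.genes) == ["a", "d"]  # strictly greater than 0.75


def test_detection_filter_zero_threshold_keeps_detected():
    genes = ["a", "b"]
    values = pd.DataFrame(np.ones((2, 5)), index=genes,
                          columns=list(SORTED_CELL_TYPES))
    det = pd.Series([0.5, 0.01], index=genes)
    ref = SortedCellExpr(values=values, detection=det)
    assert len(detection_filter(ref, min_fraction=0.0).genes) == 2


def test_detection_fallback_without_sidecar():
    genes = ["a", "b"]
    values = pd.DataFrame([[1.0] * 5, [1.0, 0.0, 1.0, 1.0, 1.0]],
                          index=genes, columns=list(SORTED_CELL_TYPES))
    ref = SortedCellExpr(values=values, detection=None)
    assert list(detection_filter(ref).genes) == ["a"]


# ------------------------------------------------------------ fold change

def test_uniform_expression_fc_one():
    genes = ["a", "b"]
    values = pd.DataFrame(np.full((2, 5), 3.0), index=genes,
                          columns=list(SORTED_CELL_TYPES))
    fc, _, _ = fold_change_vs_neurons(SortedCellExpr(values=values))
    assert np.allclose(fc.to_numpy(), 1.0)


def test_planted_astrocyte_restriction_recovered(bundle):
    filt = detection_filter(bundle.sorted_reference)
    markers = [g for g in bundle.truth.marker_catalog["astrocytes"]
               if g in filt.values.index]
    fc, _, _ = fold_change_vs_neurons(filt, gene_set=markers)
    assert (fc["astrocytes"] > 2).mean() >= 0.95


def test_top_k_default_ten(bundle):
    filt = detection_filter(bundle.sorted_reference)
    _, _, top = fold_change_vs_neurons(filt)
    assert len(top) == 10


def test_fc_antisymmetry_without_pseudocount():
    rng = np.random.default_rng(2)
    values = pd.DataFrame(rng.uniform(1, 5, size=(8, 5)),
                          index=[f"g{i}" for i in range(8)],
                          columns=list(SORTED_CELL_TYPES))
    ref = SortedCellExpr(values=values)
    fc, _, _ = fold_change_vs_neurons(ref, pseudocount=0.0)
    swapped = values.rename(columns={"neurons": "astrocytes",
                                     "astrocytes": "neurons"})
    fc2, _, _ = fold_change_vs_neurons(SortedCellExpr(values=swapped),
                                       pseudocount=0.0)
    assert np.allclose(fc["astrocytes"], 1.0 / fc2["astrocytes"])


def test_missing_neurons_column_rejected():
    values = pd.DataFrame(np.ones((2, 2)), index=["a", "b"],
                          columns=["astrocytes", "microglia"])
    with pytest.raises(ValueError, match="neurons"):
        SortedCellExpr(values=values)


# ------------------------------------------------------------ comparisons

def test_compare_sets_identical_vectors_p_one():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    assert compare_sets(v, v.copy(), method="t") == 1.0


def test_compare_sets_delegates_to_welch(rng):
    a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
    assert compare_sets(a, b, method="t") == sb.de.de_ttest(a, b)


def test_compare_sets_fisher_on_binarised(rng):
    import scipy.stats as st
    a = rng.random(40) < 0.8
    b = rng.random(40) < 0.3
    p = compare_sets(a, b, method="fisher")
    table = [[a.sum(), (~a).sum()], [b.sum(), (~b).sum()]]
    assert p == pytest.approx(st.fisher_exact(table)[1], rel=1e-12)


def test_compare_sets_null_calibrated(rng):
    hits = 0
    reps = 300
    for _ in range(reps):
        hits += compare_sets(rng.normal(size=30), rng.normal(size=30),
                             method="t") < 0.05
    assert 0.02 <= hits / reps <= 0.08
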