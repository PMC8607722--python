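"""Preprocessing and clustering: closed-form oracles and recovery."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import scburden as sb
from scburden.containers import CellByGeneCounts
from scburden.scpipe import (cluster, embed_tsne, knn_graph,
                             normalize_cpm_log, pca, residualize,
                             scale_regress, select_hvg, select_pcs_elbow)

from conftest import small_config


def make_counts(matrix, pmito=None):
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    meta = pd.DataFrame(
        {"percent_mito": pmito if pmito is not None else np.full(n, 0.05)},
        index=[f"c{i}" for i in range(n)])
    genes = [f"g{j}" for j in range(matrix.shape[1])]
    return CellByGeneCounts(sp.csr_matrix(matrix), meta, genes)


# ------------------------------------------------------------ normalisation

def test_cpm_log_closed_form():
    counts = make_counts([[1, 999_999], [10, 999_990]])
    norm = normalize_cpm_log(counts).to_dense()
    assert norm[0, 0] == pytest.approx(np.log2(2.0), abs=1e-12)  # 1 CPM of 1e6


def test_cpm_invariant_to_doubling_a_cell():
    a = make_counts([[3, 5, 7], [2, 4, 8]])
    b = make_counts([[6, 10, 14], [2, 4, 8]])
    assert np.allclose(normalize_cpm_log(a).to_dense(),
                       normalize_cpm_log(b).to_dense())


def test_cpm_matches_hand_computation_3x3():
    X = np.array([[1, 2, 3], [4, 0, 6], [7, 8, 9]], dtype=float)
    norm = normalize_cpm_log(make_counts(X)).to_dense()
    expected = np.log2(1 + 1e6 * X / X.sum(axis=1, keepdims=True))
    assert np.allclose(norm, expected, atol=1e-12)


def test_all_zero_cell_error_lists_ids():
    counts = make_counts([[0, 0], [1, 2]])
    with pytest.raises(ValueError, match="c0"):
        normalize_cpm_log(counts)


# ----------------------------------------------------------------- HVG

def test_hvg_full_request_returns_all_genes(bundle):
    norm = normalize_cpm_log(bundle.counts)
    got = select_hvg(norm, n_features=norm.n_genes)
    assert set(got) == set(norm.gene_ids)


def test_hvg_captures_planted_markers(bundle):
    norm = normalize_cpm_log(bundle.counts)
    hvg = set(select_hvg(norm, n_features=100))
    markers = set().union(*bundle.truth.marker_catalog.values())
    overlap = len(hvg & markers) / len(markers)
    assert overlap >= 0.9


def test_hvg_constant_matrix_rejected():
    counts = make_counts(np.full((10, 5), 3))
    norm = normalize_cpm_log(counts)
    with pytest.raises(ValueError, match="constant"):
        select_hvg(norm, 3)


# --------------------------------------------------------------- scaling

def test_residuals_match_normal_equations_oracle(rng):
    y = rng.normal(size=(50, 20))
    cov = rng.normal(size=(50, 2))
    got = residualize(y, cov)
    X = np.column_stack([np.ones(50), cov])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(got, y - X @ beta, atol=1e-8)


def test_expression_linear_in_covariate_residuals_vanish():
    pm = np.linspace(0.01, 0.2, 30)
    y = np.outer(2 + 3 * pm, np.ones(4))
    resid = residualize(y, pm[:, None])
    assert np.allclose(resid, 0.0, atol=1e-10)


def test_zero_variance_covariate_skipped_with_warning(rng):
    X = rng.integers(1, 50, size=(20, 6))
    counts = make_counts(X, pmito=np.full(20, 0.05))
    norm = normalize_cpm_log(counts)
    with pytest.warns(UserWarning, match="percent_mito"):
        scaled = scale_regress(norm, norm.gene_ids)
    # covariate dropped: result is just centred/z-scored values
    assert scaled.values.shape == (20, 6)
    assert np.allclose(scaled.values.mean(axis=0), 0.0, atol=1e-10)


def test_scaled_values_clipped(bundle, clustering):
    _, norm, _ = clustering
    scaled = scale_regress(norm, norm.gene_ids[:50])
    assert np.abs(scaled.values).max() <= 10.0 + 1e-12


# ------------------------------------------------------------------- PCA

def test_pca_orthonormal_loadings_and_variance(rng):
    from scburden.scpipe import ScaledMatrix
    X = rng.normal(size=(40, 12))
    X = X - X.mean(axis=0)
    sm = ScaledMatrix(values=X, gene_ids=np.arange(12), cell_ids=np.arange(40))
    res = pca(sm, 12)
    assert np.linalg.norm(res.loadings.T @ res.loadings - np.eye(12)) < 1e-8
    assert res.explained_variance.sum() == pytest.approx(
        X.var(axis=0, ddof=1).sum(), rel=1e-10)


def test_pca_matches_covariance_eigendecomposition(rng):
    from scburden.scpipe import ScaledMatrix
    X = rng.normal(size=(30, 8))
    X = X - X.mean(axis=0)
    sm = ScaledMatrix(values=X, gene_ids=np.arange(8), cell_ids=np.arange(30))
    res = pca(sm, 5)
    eigval = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1][:5]
    assert np.allclose(res.explained_variance, eigval, atol=1e-10)
    # scores are the projection onto the loadings
    assert np.allclose(res.scores, X @ res.loadings, atol=1e-10)


def test_pca_too_many_components_rejected(rng):
    from scburden.scpipe import ScaledMatrix
    sm = ScaledMatrix(values=rng.normal(size=(10, 4)),
                      gene_ids=np.arange(4), cell_ids=np.arange(10))
    with pytest.raises(ValueError):
        pca(sm, 8)


# ----------------------------------------------------------------- elbow

def test_elbow_override_honoured():
    sd = np.linspace(10, 1, 30)
    assert select_pcs_elbow(sd, override=24) == 24


def test_elbow_geometric_decay_hits_floor():
    sd = 0.5 ** np.arange(1, 31)
    assert select_pcs_elbow(sd) == 10


def test_elbow_flat_after_component_12():
    sd = np.concatenate([np.linspace(20, 5, 12), np.full(18, 5.0)])
    assert select_pcs_elbow(sd) == 12


def test_elbow_unsorted_input_rejected():
    with pytest.raises(ValueError, match="non-increasing"):
        select_pcs_elbow([5, 6, 4, 3, 2])


# ------------------------------------------------------------------ graph

def test_knn_two_separated_blobs_no_cross_edges(rng):
    a = rng.normal(size=(30, 2))
    b = rng.normal(size=(30, 2)) + 100.0
    g = knn_graph(np.vstack([a, b]), k=10)
    for e in g.es:
        assert (e.source < 30) == (e.target < 30)
    assert min(g.degree()) >= 1


def test_knn_k1_chain_matches_brute_force_nearest_neighbour():
    pts = np.array([[0.0], [1.0], [2.5], [4.5]])
    g = knn_graph(pts, k=1)
    edges = {tuple(sorted(e.tuple)) for e in g.es}
    # brute-force nearest neighbours: 0<->1, 2->1, 3->2
    assert edges == {(0, 1), (1, 2), (2, 3)}


def test_knn_k_too_large_rejected(rng):
    with pytest.raises(ValueError):
        knn_graph(rng.normal(size=(5, 2)), k=5)


# ---------------------------------------------------------------- cluster

def test_cluster_recovers_planted_types(bundle, clustering):
    labeling, _, _ = clustering
    truth = [bundle.truth.cell_labels[c] for c in bundle.counts.cell_ids]
    assert adjusted_rand_score(truth, labeling.labels) >= 0.95
    assert sum(labeling.sizes.values()) == bundle.counts.n_cells
    assert min(labeling.sizes.values()) >= 1


def test_resolution_zero_limit_single_cluster(rng):
    g = knn_graph(rng.normal(size=(40, 3)), k=5)
    lab = cluster(g, resolution=0.0, seed=0)
    assert len(lab.sizes) == 1


def test_cluster_records_resolution_in_params(rng):
    g = knn_graph(rng.normal(size=(30, 3)), k=5)
    lab = cluster(g, resolution=0.8, seed=0)
    assert lab.params["resolution"] == 0.8


def test_pipeline_determinism(bundle):
    a, _, _ = sb.scpipe.run_clustering(bundle.counts, n_hvg=300, seed=1)
    b, _, _ = sb.scpipe.run_clustering(bundle.counts, n_hvg=300, seed=1)
    assert np.array_equal(a.labels, b.labels)


# ------------------------------------------------------------------- tSNE

def test_tsne_shape_and_duplicate_proximity(rng):
    X = rng.normal(size=(60, 5))
    X[1] = X[0]  # exact duplicate rows
    emb = embed_tsne(X, perplexity=10, seed=0)
    assert emb.shape == (60, 2)
    d = np.linalg.norm(emb - emb[0], axis=1)
    d[0] = np.inf
    assert d.argmin() == 1  # the duplicate is its nearest neighbour


def test_tsne_perplexity_bound(rng):
    with pytest.raises(ValueError, match="perplexity"):
        embed_tsne(rng.normal(size=(20, 3)), perplexity=10)
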