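"""Normalisation, dimensionality reduction and graph clustering.

The preprocessing contract follows the Seurat-style convention for
droplet/nucleus RNA-seq: counts-per-million log2 normalisation, selection of
highly variable genes by standardised variance under a mean-variance trend,
per-gene residualisation on cell covariates (percentage of mitochondrial
reads) with z-scoring and clipping, PCA, an operational elbow rule for the
number of PCs, a shared-nearest-neighbour (SNN) graph, and Leiden community
detection at a resolution parameter. tSNE is provided for visualisation only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA as _SkPCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .containers import CellByGeneCounts, ClusterLabeling, ExpressionMatrix

#: SNN edges with Jaccard weight below this are pruned (toolkit convention).
SNN_PRUNE = 1.0 / 15.0


def normalize_cpm_log(counts: CellByGeneCounts) -> ExpressionMatrix:
    """log2(1 + CPM) per cell.

    value = log2(1 + 1e6 * count / cell_total). Centring and scaling are
    deferred to :func:`scale_regress`.
    """
    mat = counts.matrix.tocsr() if sp.issparse(counts.matrix) \
        else sp.csr_matrix(counts.matrix)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        bad = list(np.asarray(counts.cell_ids)[zero])
        raise ValueError(f"cells with zero total counts: {bad}")
    norm = mat.astype(float).multiply(1e6 / totals[:, None]).tocsr()
    norm.data = np.log2(1.0 + norm.data)  # zeros stay zero
    return ExpressionMatrix(norm, counts.cell_meta, counts.gene_ids)


def select_hvg(norm: ExpressionMatrix, n_features: int = 2000) -> np.ndarray:
    """Rank genes by standardised variance and return the top ``n_features``.

    Follows the vst convention: the statistic is computed on the CPM scale
    (the log2 normalisation is inverted internally, since log compression
    hides high-expression markers). A quadratic trend of log10 variance on
    log10 mean predicts each gene's expected variance; values are z-scored
    against the trend prediction, clipped at sqrt(n_cells), and the variance
    of the clipped z-scores is the ranking statistic.
    """
    if n_features > norm.n_genes:
        raise ValueError(f"n_features={n_features} exceeds {norm.n_genes} genes")
    X = np.expm1(norm.to_dense() * np.log(2.0))  # back to CPM
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    if np.allclose(var, 0.0):
        raise ValueError("constant matrix: no variable genes")
    eps = 1e-8
    usable = var > 0
    lm = np.log10(mean[usable] + eps)
    lv = np.log10(var[usable] + eps)
    coef = np.polyfit(lm, lv, deg=2)
    expected_var = np.full_like(var, eps)
    expected_var[usable] = 10.0 ** np.polyval(coef, lm)

    clip = np.sqrt(norm.n_cells)
    z = (X - mean) / np.sqrt(expected_var)
    np.clip(z, -clip, clip, out=z)
    std_var = z.var(axis=0, ddof=1)
    order = np.argsort(-std_var, kind="stable")
    return norm.gene_ids[order[:n_features]]


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of ``y`` on the covariates
    (with intercept)."""
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class ScaledMatrix:
    """Z-scored, clipped residual expression for the HVG subset."""

    values: np.ndarray  # cells x genes
    gene_ids: np.ndarray
    cell_ids: np.ndarray


def scale_regress(norm: ExpressionMatrix, hvg: Sequence[str],
                  covariates: Sequence[str] = ("percent_mito",),
                  clip: float = 10.0) -> ScaledMatrix:
    """Residualise each HVG on cell covariates, z-score and clip at +/-clip.

    Covariates with zero variance are skipped with a warning.
    """
    idx = norm.gene_index(hvg)
    X = norm.to_dense()[:, idx]
    cols = []
    for c in covariates:
        if c not in norm.cell_meta.columns:
            raise ValueError(f"covariate {c!r} missing from cell_meta")
        v = norm.cell_meta[c].to_numpy(dtype=float)
        if np.isclose(v.std(), 0.0):
            warnings.warn(f"covariate {c!r} has zero variance; skipped")
            continue
        cols.append(v)
    resid = residualize(X, np.column_stack(cols)) if cols else X - X.mean(0)
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    scaled = np.clip((resid - resid.mean(axis=0)) / sd, -clip, clip)
    return ScaledMatrix(values=scaled, gene_ids=np.asarray(hvg, dtype=object),
                        cell_ids=norm.cell_ids)


@dataclass
class PCAResult:
    scores: np.ndarray            # cells x components
    loadings: np.ndarray          # genes x components, orthonormal columns
    explained_variance: np.ndarray
    explained_sd: np.ndarray


def pca(scaled: ScaledMatrix, n_components: int) -> PCAResult:
    """Principal components of the scaled matrix (deterministic full SVD).

    Sign convention: each component is flipped so that its largest-magnitude
    loading is positive, making results reproducible up to machine precision.
    """
    X = scaled.values
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min{X.shape}")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return PCAResult(scores=scores * flip, loadings=loadings * flip,
                     explained_variance=model.explained_variance_,
                     explained_sd=np.sqrt(model.explained_variance_))


def select_pcs_elbow(explained_sd: Sequence[float],
                     override: Optional[int] = None,
                     min_pcs: int = 10, tol_frac: float = 0.001) -> int:
    """Operational elbow rule: last PC before the spectrum plateaus.

    Returns ``override`` verbatim when given (paper-parity runs). Otherwise
    k is the smallest i such that every subsequent drop sd_j - sd_{j+1}
    (j >= i) is below ``tol_frac`` of the total sd, floored at ``min_pcs``.
    """
    if override is not None:
        return int(override)
    sd = np.asarray(explained_sd, dtype=float)
    if sd.size < 5:
        raise ValueError("need at least 5 components for the elbow rule")
    if np.any(np.diff(sd) > 1e-10):
        raise ValueError("explained sd must be non-increasing (sorted)")
    drops = -np.diff(sd)
    tol = tol_frac * sd.sum()
    small = drops < tol
    k = sd.size
    for i in range(small.size):
        if small[i:].all():
            k = i + 1
            break
    return int(min(max(k, min_pcs), sd.size))


def knn_graph(scores: np.ndarray, k: int = 20) -> ig.Graph:
    """Shared-nearest-neighbour graph on PCA scores.

    Each cell's neighbourhood is itself plus its k nearest neighbours
    (Euclidean); the SNN weight of an edge is the Jaccard overlap of the two
    neighbourhoods, pruned below 1/15 — except that every cell keeps its
    strongest edge, so no node is isolated.
    """
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be below the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)  # includes self in column 0
    neigh = [set(row) | {i} for i, row in enumerate(idx)]

    cand = {}
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j == i:
                continue
            a, b = (i, j) if i < j else (j, i)
            if (a, b) not in cand:
                inter = len(neigh[a] & neigh[b])
                union = len(neigh[a] | neigh[b])
                cand[(a, b)] = inter / union

    keep = {e: w for e, w in cand.items() if w >= SNN_PRUNE}
    # rescue: every node keeps its strongest candidate edge
    best = {}
    for (a, b), w in cand.items():
        for v in (a, b):
            if v not in best or w > best[v][1]:
                best[v] = ((a, b), w)
    for v, (e, w) in best.items():
        keep.setdefault(e, w)

    g = ig.Graph(n=n, edges=list(keep.keys()), directed=False)
    g.es["weight"] = list(keep.values())
    return g


def cluster(graph: ig.Graph, resolution: float = 0.8,
            seed: int = 0) -> ClusterLabeling:
    """Leiden community detection on the SNN graph.

    Uses the RB-configuration quality function so the resolution parameter
    has the usual modularity semantics. Labels are relabelled by decreasing
    cluster size (ties broken by original label).
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution,
        seed=int(seed), n_iterations=-1)
    raw = np.asarray(part.membership)
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(x)] for x in raw])
    return ClusterLabeling(labels=labels,
                           params={"resolution": resolution, "seed": seed,
                                   "knn_k": None, "n_pcs": None})


def embed_tsne(scores: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """2-D tSNE of the PCA scores (visualisation only)."""
    n = scores.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ValueError(f"perplexity={perplexity} too large for {n} cells")
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
               init="pca").fit_transform(scores)
    if not np.all(np.isfinite(emb)):
        raise RuntimeError("non-finite tSNE coordinates")
    return emb


def run_clustering(counts: CellByGeneCounts, n_hvg: int = 2000,
                   n_pcs: Optional[int] = None, knn_k: int = 20,
                   resolution: float = 0.8, seed: int = 0,
                   covariates: Sequence[str] = ("percent_mito",)
                   ) -> tuple:
    """Counts -> cluster labels, end to end.

    Returns (labels, normalised matrix, pca result). ``n_pcs=None`` applies
    the elbow rule; an integer overrides it.
    """
    norm = normalize_cpm_log(counts)
    hvg = select_hvg(norm, min(n_hvg, norm.n_genes))
    scaled = scale_regress(norm, hvg, covariates=covariates)
    max_pcs = min(50, min(scaled.values.shape) - 1)
    pcs = pca(scaled, max_pcs)
    k = select_pcs_elbow(pcs.explained_sd, override=n_pcs)
    k = min(k, max_pcs)
    graph = knn_graph(pcs.scores[:, :k], k=knn_k)
    labeling = cluster(graph, resolution=resolution, seed=seed)
    labeling.params.update({"n_pcs": k, "knn_k": knn_k})
    return labeling, norm, pcs
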