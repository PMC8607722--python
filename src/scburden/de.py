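"""One-vs-rest differential expression under four tests, with consensus calls.

The four tests are the classic marker-detection quartet: Wilcoxon rank-sum,
Welch's t, a bimodal likelihood-ratio test (point mass at zero plus a normal
on the positive values), and a hurdle test in the MAST family (logistic
detection part plus Gaussian positive part, chi-square statistics summed).
A gene is a consensus DEG for a cluster iff its Bonferroni-adjusted p-value
is below the threshold in all four tests; consensus lists are ordered by
decreasing log2 fold change.

Scalar test functions (``de_*``) operate on two 1-D arrays of normalised
expression; ``run_consensus_de`` runs vectorised versions of the same
formulas across all genes of a matrix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .containers import ClusterLabeling, ExpressionMatrix

TEST_NAMES = ("wilcox", "ttest", "bimod", "hurdle")


# ---------------------------------------------------------------- wilcoxon

def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all assignments of the
    pooled midranks to the first group."""
    pooled = np.concatenate([a, b])
    ranks = st.rankdata(pooled)  # midranks handle ties
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    e = ranks.sum() * n_a / len(pooled)
    d_obs = abs(w_obs - e)
    total = extreme = 0
    for comb in combinations(range(len(pooled)), n_a):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - e) >= d_obs - 1e-12:
            extreme += 1
    return extreme / total


def de_wilcoxon(in_values: Sequence[float], out_values: Sequence[float]
                ) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have at most 8 observations,
    tie-corrected normal approximation otherwise. Degenerate all-tied input
    returns p = 1.
    """
    a = np.asarray(in_values, dtype=float)
    b = np.asarray(out_values, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 cells")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 1.0
    if a.size <= 8 and b.size <= 8:
        return _rank_sum_exact(a, b)
    res = st.mannwhitneyu(a, b, alternative="two-sided",
                          method="asymptotic", use_continuity=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


# ------------------------------------------------------------------ t test

def de_ttest(in_values: Sequence[float], out_values: Sequence[float]
             ) -> float:
    """Welch's two-sided t-test p-value; zero pooled variance degenerates to
    p = 1 for equal means and p = 0 otherwise."""
    a = np.asarray(in_values, dtype=float)
    b = np.asarray(out_values, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 cells")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(st.ttest_ind(a, b, equal_var=False).pvalue)
    return 1.0 if np.isnan(p) else p


# ------------------------------------------------------------------- bimod

def _bernoulli_ll(k: float, n: float) -> float:
    """Maximised Bernoulli log-likelihood of k successes in n trials."""
    return float(xlogy(k, k / n) + xlogy(n - k, 1.0 - k / n)) if n > 0 else 0.0


def bimod_loglik(a: np.ndarray, b: np.ndarray, shared: bool) -> tuple:
    """Maximised log-likelihood of the zero-inflated normal model.

    ``shared=True`` fits one (pi, mu, sigma) to the pooled data (null);
    ``shared=False`` fits per-group (pi, mu) with a shared sigma
    (alternative). Returns (loglik, n_positive_total, sigma_hat).
    """
    pos_a, pos_b = a[a > 0], b[b > 0]
    k_tot = pos_a.size + pos_b.size
    if shared:
        pooled = np.concatenate([a, b])
        pos = pooled[pooled > 0]
        ll = _bernoulli_ll(pos.size, pooled.size)
        if pos.size >= 2:
            mu = pos.mean()
            sig2 = max(np.mean((pos - mu) ** 2), 1e-12)
            ll += -0.5 * pos.size * (np.log(2 * np.pi * sig2) + 1.0)
        return ll, k_tot, None
    ll = _bernoulli_ll(pos_a.size, a.size) + _bernoulli_ll(pos_b.size, b.size)
    if k_tot >= 2:
        rss = 0.0
        for pos in (pos_a, pos_b):
            if pos.size:
                rss += np.sum((pos - pos.mean()) ** 2)
        sig2 = max(rss / k_tot, 1e-12)
        ll += -0.5 * k_tot * (np.log(2 * np.pi * sig2) + 1.0)
        return ll, k_tot, np.sqrt(sig2)
    return ll, k_tot, None


def de_bimod(in_values: Sequence[float], out_values: Sequence[float]
             ) -> float:
    """Likelihood-ratio test of the zero-inflated (bimodal) model.

    Null: shared (pi, mu, sigma). Alternative: per-group (pi, mu), shared
    sigma. 2*delta-loglik ~ chi-square with 2 df. With no positive values in
    either group the test reduces to the detection-proportion comparison
    (1 df).
    """
    a = np.asarray(in_values, dtype=float)
    b = np.asarray(out_values, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 cells")
    ll0, k_tot, _ = bimod_loglik(a, b, shared=True)
    ll1, _, _ = bimod_loglik(a, b, shared=False)
    stat = max(2.0 * (ll1 - ll0), 0.0)
    df = 2 if k_tot >= 2 else 1
    return float(st.chi2.sf(stat, df)) if stat > 0 else 1.0


# ------------------------------------------------------------------ hurdle

def _detection_lrt(k_a: float, n_a: float, k_b: float, n_b: float
                   ) -> tuple:
    """Logistic-regression LRT of detection on group (closed form for a
    single binary covariate). Complete separation (a group rate of 0 or 1)
    falls back to a Haldane-corrected fit; returns (stat, separated)."""
    separated = k_a in (0, n_a) or k_b in (0, n_b)
    if separated:
        k_a, n_a = k_a + 0.5, n_a + 1.0
        k_b, n_b = k_b + 0.5, n_b + 1.0
    ll_alt = _bernoulli_ll(k_a, n_a) + _bernoulli_ll(k_b, n_b)
    ll_null = _bernoulli_ll(k_a + k_b, n_a + n_b)
    return max(2.0 * (ll_alt - ll_null), 0.0), separated


def de_hurdle(in_values: Sequence[float], out_values: Sequence[float],
              return_details: bool = False):
    """Hurdle (MAST-family) test: detection part + positive part.

    The logistic LRT of detection on group (1 df) and the Gaussian LRT of
    the positive values on group (1 df) are summed; p is the chi-square
    upper tail with df = number of contributing parts. The positive part is
    dropped when fewer than two positive values exist in either group.
    """
    a = np.asarray(in_values, dtype=float)
    b = np.asarray(out_values, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 cells")
    pos_a, pos_b = a[a > 0], b[b > 0]
    det_stat, separated = _detection_lrt(pos_a.size, a.size,
                                         pos_b.size, b.size)
    stat, df = det_stat, 1
    if pos_a.size >= 2 and pos_b.size >= 2:
        pos = np.concatenate([pos_a, pos_b])
        rss0 = np.sum((pos - pos.mean()) ** 2)
        rss1 = (np.sum((pos_a - pos_a.mean()) ** 2)
                + np.sum((pos_b - pos_b.mean()) ** 2))
        if rss1 > 0:
            stat += pos.size * np.log(rss0 / rss1)
            df += 1
        elif rss0 > 0:  # perfect within-group fit, real between-group spread
            stat += np.inf
            df += 1
    p = float(st.chi2.sf(stat, df)) if stat > 0 else 1.0
    if return_details:
        return p, {"separated": separated, "df": df, "stat": float(stat)}
    return p


# -------------------------------------------------------------- adjustment

def adjust(p_values: Sequence[float], method: str = "bonferroni",
           m: Optional[int] = None) -> np.ndarray:
    """Multiple-testing adjustment: Bonferroni (min(1, m*p)) or
    Benjamini-Hochberg step-up."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if method == "bonferroni":
        m = len(p) if m is None else m
        return np.minimum(1.0, m * p)
    if method in ("bh", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


# ------------------------------------------------------- vectorised engine

def _welch_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = st.ttest_ind(A, B, axis=0, equal_var=False).pvalue
    both_const = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    eq = np.isclose(A.mean(axis=0), B.mean(axis=0))
    p = np.where(both_const, np.where(eq, 1.0, 0.0), p)
    return np.nan_to_num(p, nan=1.0)


def _wilcox_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = st.mannwhitneyu(A, B, axis=0, alternative="two-sided",
                            method="asymptotic",
                            use_continuity=False).pvalue
    return np.nan_to_num(np.minimum(p, 1.0), nan=1.0)


def _bimod_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    def moments(X):
        M = X > 0
        k = M.sum(axis=0).astype(float)
        s = X.sum(axis=0)
        ss = (X ** 2).sum(axis=0)
        return k, s, ss

    ka, sa, ssa = moments(A)
    kb, sb, ssb = moments(B)
    na, nb = float(A.shape[0]), float(B.shape[0])
    kt, stot, sstot = ka + kb, sa + sb, ssa + ssb

    def bern(k, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            return xlogy(k, k / n) + xlogy(n - k, 1 - k / n)

    # null: pooled pi, mu, sigma
    ll0 = bern(kt, na + nb)
    mu0 = np.divide(stot, kt, out=np.zeros_like(stot), where=kt > 0)
    sig0 = np.maximum(np.divide(sstot, kt, out=np.zeros_like(stot),
                                where=kt > 0) - mu0 ** 2, 1e-12)
    has = kt >= 2
    ll0 = ll0 + np.where(has, -0.5 * kt * (np.log(2 * np.pi * sig0) + 1), 0.0)

    # alternative: per-group pi, mu; shared sigma
    ll1 = bern(ka, na) + bern(kb, nb)
    mua = np.divide(sa, ka, out=np.zeros_like(sa), where=ka > 0)
    mub = np.divide(sb, kb, out=np.zeros_like(sb), where=kb > 0)
    rss = (ssa - ka * mua ** 2) + (ssb - kb * mub ** 2)
    sig1 = np.maximum(np.divide(rss, kt, out=np.full_like(rss, 1e-12),
                                where=kt > 0), 1e-12)
    ll1 = ll1 + np.where(has, -0.5 * kt * (np.log(2 * np.pi * sig1) + 1), 0.0)

    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    df = np.where(has, 2.0, 1.0)
    return np.where(stat > 0, st.chi2.sf(stat, df), 1.0)


def _hurdle_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na, nb = float(A.shape[0]), float(B.shape[0])
    Ma, Mb = A > 0, B > 0
    ka = Ma.sum(axis=0).astype(float)
    kb = Mb.sum(axis=0).astype(float)

    sepa = (ka == 0) | (ka == na) | (kb == 0) | (kb == nb)
    ka_c = np.where(sepa, ka + 0.5, ka)
    na_c = np.where(sepa, na + 1.0, na)
    kb_c = np.where(sepa, kb + 0.5, kb)
    nb_c = np.where(sepa, nb + 1.0, nb)

    def bern(k, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            return xlogy(k, k / n) + xlogy(n - k, 1 - k / n)

    det = np.maximum(2.0 * (bern(ka_c, na_c) + bern(kb_c, nb_c)
                            - bern(ka_c + kb_c, na_c + nb_c)), 0.0)

    sa, ssa = A.sum(axis=0), (A ** 2).sum(axis=0)
    sb, ssb = B.sum(axis=0), (B ** 2).sum(axis=0)
    mua = np.divide(sa, ka, out=np.zeros_like(sa), where=ka > 0)
    mub = np.divide(sb, kb, out=np.zeros_like(sb), where=kb > 0)
    kt = ka + kb
    mu0 = np.divide(sa + sb, kt, out=np.zeros_like(sa), where=kt > 0)
    rss0 = (ssa + ssb) - kt * mu0 ** 2
    rss1 = (ssa - ka * mua ** 2) + (ssb - kb * mub ** 2)
    cont_ok = (ka >= 2) & (kb >= 2) & (rss1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cont = np.where(cont_ok, kt * np.log(rss0 / np.maximum(rss1, 1e-300)),
                        0.0)
    cont = np.maximum(np.nan_to_num(cont, nan=0.0), 0.0)

    stat = det + cont
    df = 1.0 + cont_ok.astype(float)
    return np.where(stat > 0, st.chi2.sf(stat, df), 1.0)


_BATCH = {"wilcox": _wilcox_batch, "ttest": _welch_batch,
          "bimod": _bimod_batch, "hurdle": _hurdle_batch}


# ------------------------------------------------------------- orchestration

@dataclass
class ConsensusDEG:
    """Per-cluster consensus DEG lists, ordered by decreasing log2 FC."""

    tables: Dict[int, pd.DataFrame] = field(default_factory=dict)
    threshold: float = 1e-3

    def genes(self, cluster: int) -> list:
        return list(self.tables.get(cluster, pd.DataFrame(
            columns=["gene"]))["gene"])

    def gene_sets(self) -> Dict[int, set]:
        return {c: set(t["gene"]) for c, t in self.tables.items()}


def log2_fold_change(A: np.ndarray, B: np.ndarray,
                     pseudocount: float = 1.0) -> np.ndarray:
    """log2 ratio of group means on the expm scale (2**x - 1), with a
    pseudocount on both means."""
    m_in = np.expm1(A * np.log(2)).mean(axis=0)
    m_out = np.expm1(B * np.log(2)).mean(axis=0)
    return np.log2((m_in + pseudocount) / (m_out + pseudocount))


def run_de(norm: ExpressionMatrix, labeling: ClusterLabeling,
           min_pct: float = 0.1, min_abs_log2fc: float = 0.25,
           prefilter: bool = True) -> Dict[int, pd.DataFrame]:
    """One-vs-rest DE for every cluster under the four tests.

    With ``prefilter`` (toolkit convention) a gene is tested only when it is
    detected in at least ``min_pct`` of in-cluster cells and its absolute
    log2 fold change is at least ``min_abs_log2fc``. Bonferroni adjustment
    uses m = number of genes tested in that cluster.
    """
    labels = np.asarray(labeling.labels)
    if labels.size != norm.n_cells:
        raise ValueError("labeling does not cover the matrix")
    X = norm.to_dense()
    out = {}
    for c in labeling.cluster_ids:
        mask = labels == c
        A, B = X[mask], X[~mask]
        if A.shape[0] < 3 or B.shape[0] < 3:
            continue
        fc = log2_fold_change(A, B)
        pct_in = (A > 0).mean(axis=0)
        pct_out = (B > 0).mean(axis=0)
        tested = np.ones(norm.n_genes, dtype=bool)
        if prefilter:
            tested = (pct_in >= min_pct) & (np.abs(fc) >= min_abs_log2fc)
        if not tested.any():
            out[c] = pd.DataFrame(columns=["gene", "log2_fc", "pct_in",
                                           "pct_out"])
            continue
        tbl = pd.DataFrame({"gene": norm.gene_ids[tested],
                            "log2_fc": fc[tested],
                            "pct_in": pct_in[tested],
                            "pct_out": pct_out[tested]})
        m = int(tested.sum())
        for name in TEST_NAMES:
            p = _BATCH[name](A[:, tested], B[:, tested])
            tbl[f"p_{name}"] = p
            tbl[f"p_adj_{name}"] = adjust(p, "bonferroni", m=m)
        out[c] = tbl
    return out


def consensus(de_tables: Dict[int, pd.DataFrame],
              threshold: float = 1e-3) -> ConsensusDEG:
    """Keep genes with all four adjusted p-values below the threshold."""
    result = {}
    for c, tbl in de_tables.items():
        cols = [f"p_adj_{t}" for t in TEST_NAMES]
        missing = [t for t, col in zip(TEST_NAMES, cols)
                   if col not in tbl.columns]
        if missing and len(tbl):
            raise ValueError(f"cluster {c}: missing test(s) {missing}")
        if not len(tbl):
            result[c] = tbl.copy()
            continue
        keep = np.ones(len(tbl), dtype=bool)
        for col in cols:
            keep &= tbl[col].to_numpy() < threshold
        sub = tbl[keep].sort_values("log2_fc", ascending=False,
                                    kind="stable").reset_index(drop=True)
        result[c] = sub
    return ConsensusDEG(tables=result, threshold=threshold)


def run_consensus_de(norm: ExpressionMatrix, labeling: ClusterLabeling,
                     threshold: float = 1e-3, **kwargs) -> ConsensusDEG:
    """Convenience: one-vs-rest four-test DE, then the consensus call."""
    return consensus(run_de(norm, labeling, **kwargs), threshold=threshold)
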