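"""Developmental association and sorted-cell-type replication.

Two analyses live here. The stage/region association asks, for every
(region, period) cell of a gene x (16 regions x 3 periods) expression grid,
whether high expression within the cell co-occurs with membership in a
variant gene set: expression is binarised at a within-cell quantile
(default the median) and crossed with variant membership in a 2x2 Fisher
test, yielding an odds ratio and p per grid cell. The quantile-binarised
construction is this package's operationalisation of the association and
the quantile is exposed.

The replication analysis works on a gene x sorted-cell-type mean-expression
table: a detection filter (genes expressed in more than 75% of cells,
interpreted as detection fraction > 0.75), fold change of every cell type
versus neurons with a pseudocount, and the top-k genes by maximal
non-neuronal fold change (default k = 10).
"""
from __future__ import annotations

from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import EnrichmentResult, SortedCellExpr, SpatioTemporalExpr
from .de import de_ttest
from .enrich import odds_ratio


def stage_region_association(gene_set: Iterable[str],
                             st_expr: SpatioTemporalExpr,
                             variant_genes: Iterable[str],
                             expr_quantile: float = 0.5
                             ) -> Dict[Tuple[str, str], EnrichmentResult]:
    """Per (region, period): 2x2 of high expression x variant membership.

    Restricted to ``gene_set`` (which must be present in the grid); a grid
    cell with all-equal expression is flagged degenerate.
    """
    genes = [g for g in gene_set]
    missing = set(genes) - set(st_expr.genes)
    if missing:
        raise ValueError(f"genes absent from the grid: {sorted(missing)[:5]}")
    variant = set(variant_genes)
    sub = st_expr.values.loc[genes]
    is_var = np.array([g in variant for g in genes])

    out = {}
    for region in st_expr.regions:
        for period in st_expr.periods:
            v = sub[(region, period)].to_numpy(dtype=float)
            if np.allclose(v, v[0]):
                out[(region, period)] = EnrichmentResult(
                    set_a_name=f"{region}:{period}", set_b_name="variant",
                    universe_size=len(genes), a_size=0,
                    b_size=int(is_var.sum()), overlap=0, odds_ratio=np.nan,
                    p=np.nan, p_adj=np.nan, method="fisher", degenerate=True)
                continue
            thr = np.quantile(v, expr_quantile)
            high = v >= thr
            n11 = int(np.sum(high & is_var))
            n10 = int(np.sum(high & ~is_var))
            n01 = int(np.sum(~high & is_var))
            n00 = int(np.sum(~high & ~is_var))
            p = float(st.fisher_exact([[n11, n10], [n01, n00]],
                                      alternative="two-sided")[1])
            out[(region, period)] = EnrichmentResult(
                set_a_name=f"{region}:{period}", set_b_name="variant",
                universe_size=len(genes), a_size=int(high.sum()),
                b_size=int(is_var.sum()), overlap=n11,
                odds_ratio=odds_ratio(n11, n10, n01, n00), p=p, p_adj=p,
                method="fisher")
    return out


def association_grid(results: Dict[Tuple[str, str], EnrichmentResult]
                     ) -> pd.DataFrame:
    """Long-format table of the association results (heatmap-ready)."""
    rows = [{"region": r, "period": per, "odds_ratio": res.odds_ratio,
             "p": res.p, "degenerate": res.degenerate}
            for (r, per), res in results.items()]
    return pd.DataFrame(rows)


def argmax_period(results: Dict[Tuple[str, str], EnrichmentResult]
                  ) -> Optional[str]:
    """Period of the grid cell with the maximal (non-degenerate) OR."""
    best, best_or = None, -np.inf
    for (region, period), res in results.items():
        if res.degenerate or not np.isfinite(res.odds_ratio):
            continue
        if res.odds_ratio > best_or:
            best, best_or = period, res.odds_ratio
    return best


def detection_filter(sorted_expr: SortedCellExpr,
                     min_fraction: float = 0.75) -> SortedCellExpr:
    """Retain genes detected in more than ``min_fraction`` of cells.

    When no detection sidecar exists, retain genes with nonzero expression
    in every cell type.
    """
    if sorted_expr.detection is not None:
        keep = sorted_expr.detection > min_fraction
        det = sorted_expr.detection[keep]
    else:
        keep = (sorted_expr.values > 0).all(axis=1)
        det = None
    return SortedCellExpr(values=sorted_expr.values[keep.to_numpy()],
                          species=sorted_expr.species, detection=det)


def fold_change_vs_neurons(sorted_expr: SortedCellExpr,
                           gene_set: Optional[Iterable[str]] = None,
                           pseudocount: float = 0.01, k: int = 10
                           ) -> Tuple[pd.DataFrame, pd.DataFrame, list]:
    """Per-gene fold change of every cell type versus neurons.

    FC(g, t) = (expr(g, t) + pc) / (expr(g, neurons) + pc). Returns the FC
    table, the mean-expression table it was computed from, and the top-k
    genes ranked by maximal non-neuronal FC.
    """
    df = sorted_expr.values
    if gene_set is not None:
        genes = [g for g in gene_set if g in df.index]
        df = df.loc[genes]
    ref = df["neurons"] + pseudocount
    fc = (df + pseudocount).div(ref, axis=0)
    non_neuronal = [c for c in fc.columns if c != "neurons"]
    top = list(fc[non_neuronal].max(axis=1)
               .sort_values(ascending=False, kind="stable")[:k].index)
    return fc, df, top


def compare_sets(values_a, values_b, method: str = "t") -> float:
    """Dispatch to the appropriate comparison of two samples.

    ``method="t"``: Welch t-test on the two value vectors (mean expression
    or fold change). ``method="fisher"``: the two vectors are booleans and
    the 2x2 crosstab goes to the two-sided Fisher exact test.
    """
    if method == "t":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test requires >= 2 values per group")
        if a.size < 3 or b.size < 3:  # delegate contract requires >= 3
            if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
                return 1.0 if a.mean() == b.mean() else 0.0
            return float(st.ttest_ind(a, b, equal_var=False).pvalue)
        return de_ttest(a, b)
    if method == "fisher":
        a = np.asarray(values_a, dtype=bool)
        b = np.asarray(values_b, dtype=bool)
        table = [[int(np.sum(a)), int(np.sum(~a))],
                 [int(np.sum(b)), int(np.sum(~b))]]
        return float(st.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown method {method!r}")
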