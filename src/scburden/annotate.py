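"""Cluster annotation from marker evidence.

Cell identity of a transcriptomic cluster is called from two independent
lines of evidence: (i) the composition of its top-n consensus DEGs with
respect to a curated marker catalogue (neurons, astrocytes,
oligodendrocytes, microglia, OPC), and (ii) the mean normalised expression
of each type's markers over the cluster's cells. A cluster is called a type
only when the composition argmax reaches a threshold tau AND the expression
argmax agrees; everything else is "unassigned" — mirroring the fact that
visual-inspection annotation leaves some clusters uncalled. The conjunction
rule and tau are this package's operationalisation of that judgement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .containers import ClusterLabeling, ExpressionMatrix
from .de import ConsensusDEG

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class CellTypeCall:
    """Identity call for one cluster with its supporting evidence."""

    cluster: int
    call: str
    composition: Dict[str, float] = field(default_factory=dict)
    mean_marker_expr: Dict[str, float] = field(default_factory=dict)
    n_effective: int = 0
    tie: bool = False


def mean_marker_expression(norm: ExpressionMatrix, labeling: ClusterLabeling,
                           catalog: Mapping[str, set]) -> pd.DataFrame:
    """Cluster x cell-type matrix of mean marker expression.

    Markers absent from the matrix are dropped (logged); overlapping markers
    between types are allowed but logged.
    """
    present = set(norm.gene_ids)
    seen = {}
    for t, genes in catalog.items():
        for g in genes:
            if g in seen:
                logger.info("marker %s shared by %s and %s", g, seen[g], t)
            seen[g] = t
    X = norm.to_dense()
    labels = np.asarray(labeling.labels)
    rows = []
    for c in labeling.cluster_ids:
        mask = labels == c
        row = {}
        for t, genes in catalog.items():
            keep = sorted(g for g in genes if g in present)
            dropped = len(genes) - len(keep)
            if dropped:
                logger.info("cluster %s: %d %s markers absent from matrix",
                            c, dropped, t)
            if not keep:
                row[t] = 0.0
                continue
            idx = norm.gene_index(keep)
            row[t] = float(X[np.ix_(mask, idx)].mean())
        rows.append(pd.Series(row, name=c))
    return pd.DataFrame(rows)


def top_deg_composition(consensus: ConsensusDEG, catalog: Mapping[str, set],
                        n: int = 20) -> pd.DataFrame:
    """Fraction of each cluster's top-n DEGs falling in each marker set.

    Consensus tables are already ranked by decreasing fold change. Clusters
    with fewer than n DEGs use all of them; ``n_effective`` records how many.
    The remainder (genes in no marker set) is reported as ``others``.
    """
    rows = []
    for c, tbl in consensus.tables.items():
        top = list(tbl["gene"][:n])
        n_eff = len(top)
        row = {}
        assigned = 0
        for t, genes in catalog.items():
            k = sum(1 for g in top if g in genes)
            row[t] = k / n_eff if n_eff else 0.0
            assigned += k
        row["others"] = max(0.0, 1.0 - (assigned / n_eff)) if n_eff else 1.0
        row["n_effective"] = n_eff
        rows.append(pd.Series(row, name=c))
    return pd.DataFrame(rows)


def assign_cell_type(composition: Mapping[str, float],
                     mean_marker_expr: Mapping[str, float],
                     cluster: int = 0, tau: float = 0.25) -> CellTypeCall:
    """Conjunction rule: composition argmax >= tau AND expression argmax
    agrees; otherwise unassigned (ties are unassigned with a tie flag)."""
    types = [t for t in composition if t not in ("others", "n_effective")]
    comp = {t: composition[t] for t in types}
    expr = {t: mean_marker_expr.get(t, 0.0) for t in types}
    n_eff = int(composition.get("n_effective", 0))

    best_c = max(comp.values(), default=0.0)
    cand_c = [t for t in types if comp[t] == best_c]
    best_e = max(expr.values(), default=0.0)
    cand_e = [t for t in types if expr[t] == best_e]

    tie = len(cand_c) > 1 or len(cand_e) > 1
    call = UNASSIGNED
    if not tie and best_c >= tau and cand_c[0] == cand_e[0]:
        call = cand_c[0]
    return CellTypeCall(cluster=cluster, call=call, composition=dict(comp),
                        mean_marker_expr=dict(expr), n_effective=n_eff,
                        tie=tie)


def assign_all(composition: pd.DataFrame, mean_expr: pd.DataFrame,
               tau: float = 0.25) -> Dict[int, CellTypeCall]:
    """Apply the conjunction rule to every cluster."""
    calls = {}
    for c in composition.index:
        calls[c] = assign_cell_type(composition.loc[c].to_dict(),
                                    mean_expr.loc[c].to_dict(),
                                    cluster=c, tau=tau)
    return calls
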