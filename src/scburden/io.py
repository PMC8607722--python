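"""Readers and writers for the pipeline's plain-text formats.

Counts travel as an MTX triplet directory (matrix.mtx + barcodes.tsv +
features.tsv + cell_meta.tsv); gene sets and marker catalogues as GMT;
variants, pLI, exon models, the spatiotemporal grid and the sorted-cell
reference as tab-separated tables with header rows; ground truth as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .containers import (CellByGeneCounts, ExonRecord, GeneSet, STAGES,
                         SortedCellExpr, SpatioTemporalExpr, VariantRecord)
from .synth import GroundTruth

VARIANT_COLUMNS = ["variant_id", "gene", "effect", "inheritance", "case_id"]
EXON_COLUMNS = ["gene", "exon_index", "length_bp", "nonsyn_count",
                "expr_PN", "expr_EC", "expr_AD"]


# ------------------------------------------------------------------ counts

def write_counts_dir(counts: CellByGeneCounts, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = counts.matrix if sp.issparse(counts.matrix) \
        else sp.csr_matrix(counts.matrix)
    sio.mmwrite(str(outdir / "matrix.mtx"), mat.T.tocoo())  # genes x cells
    pd.Series(counts.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(counts.gene_ids).to_csv(outdir / "features.tsv", sep="\t",
                                      index=False, header=False)
    counts.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t",
                           float_format="%.17g")


def read_counts_dir(indir) -> CellByGeneCounts:
    indir = Path(indir)
    mat = sp.csr_matrix(sio.mmread(str(indir / "matrix.mtx")).T)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t",
                           header=None)[0].tolist()
    features = pd.read_csv(indir / "features.tsv", sep="\t",
                           header=None)[0].tolist()
    meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t", index_col=0,
                       float_precision="round_trip")
    meta = meta.loc[barcodes]
    return CellByGeneCounts(mat.astype(np.int64), meta, features)


# --------------------------------------------------------------------- GMT

def write_gmt(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.provenance or '.'}\t{genes}\n")


def read_gmt(path) -> List[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, provenance, genes = parts[0], parts[1], parts[2:]
            sets.append(GeneSet(name=name, genes=set(g for g in genes if g),
                                provenance="" if provenance == "." else
                                provenance))
    return sets


# ---------------------------------------------------------------- variants

def write_variants(records: Iterable[VariantRecord], path) -> None:
    pd.DataFrame([{c: getattr(v, c) for c in VARIANT_COLUMNS}
                  for v in records]).to_csv(path, sep="\t", index=False)


def read_variants(path) -> List[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns {missing}")
    return [VariantRecord(**row[VARIANT_COLUMNS].to_dict())
            for _, row in df.iterrows()]


# ------------------------------------------------------------------- exons

def write_exons(records: Iterable[ExonRecord], path) -> None:
    rows = [{"gene": e.gene, "exon_index": e.exon_index,
             "length_bp": e.length_bp, "nonsyn_count": e.nonsyn_count,
             **{f"expr_{s}": e.expr[s] for s in STAGES}} for e in records]
    pd.DataFrame(rows, columns=EXON_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_exons(path) -> List[ExonRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [ExonRecord(gene=str(r.gene), exon_index=int(r.exon_index),
                       length_bp=int(r.length_bp),
                       nonsyn_count=int(r.nonsyn_count),
                       expr={s: float(getattr(r, f"expr_{s}"))
                             for s in STAGES})
            for r in df.itertuples(index=False)]


# ------------------------------------------------------------- flat tables

def write_pli(pli: pd.DataFrame, path) -> None:
    pli.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pli(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_spatiotemporal(st_expr: SpatioTemporalExpr, path) -> None:
    long = st_expr.values.stack(["region", "period"], future_stack=True) \
        .rename("value").reset_index()
    long.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_spatiotemporal(path) -> SpatioTemporalExpr:
    long = pd.read_csv(path, sep="\t", float_precision="round_trip")
    wide = long.pivot_table(index="gene", columns=["region", "period"],
                            values="value", sort=False)
    regions = tuple(dict.fromkeys(long["region"]))
    periods = tuple(dict.fromkeys(long["period"]))
    wide = wide.reindex(columns=pd.MultiIndex.from_product(
        [regions, periods], names=["region", "period"]))
    return SpatioTemporalExpr(values=wide, regions=regions, periods=periods)


def write_sorted_reference(ref: SortedCellExpr, path) -> None:
    df = ref.values.copy()
    if ref.detection is not None:
        df["detection"] = ref.detection
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_sorted_reference(path, species: str = "unknown") -> SortedCellExpr:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    det = df.pop("detection") if "detection" in df.columns else None
    return SortedCellExpr(values=df, species=species, detection=det)


# ------------------------------------------------------------ ground truth

def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "cell_labels": truth.cell_labels,
        "marker_catalog": {k: sorted(v)
                           for k, v in truth.marker_catalog.items()},
        "critical_exon_flags": sorted([list(t)
                                       for t in truth.critical_exon_flags]),
        "high_pli_genes": sorted(truth.high_pli_genes),
        "enriched_variant_genes": sorted(truth.enriched_variant_genes),
        "prenatal_biased_genes": sorted(truth.prenatal_biased_genes),
        "lof_genes": sorted(truth.lof_genes),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        cell_labels=d["cell_labels"],
        marker_catalog={k: set(v) for k, v in d["marker_catalog"].items()},
        critical_exon_flags={(g, int(i), s)
                             for g, i, s in d["critical_exon_flags"]},
        high_pli_genes=set(d["high_pli_genes"]),
        enriched_variant_genes=set(d["enriched_variant_genes"]),
        prenatal_biased_genes=set(d["prenatal_biased_genes"]),
        lof_genes=set(d["lof_genes"]))


def write_bundle(bundle, outdir) -> None:
    """Write every generated input of a SynthBundle to one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_dir(bundle.counts, outdir / "counts")
    write_variants(bundle.variants, outdir / "variants.tsv")
    write_exons(bundle.exons, outdir / "exons.tsv")
    write_pli(bundle.pli, outdir / "pli.tsv")
    write_spatiotemporal(bundle.spatiotemporal, outdir / "spatiotemporal.tsv")
    write_sorted_reference(bundle.sorted_reference, outdir / "sorted_cells.tsv")
    write_gmt([GeneSet(t, g, "planted markers")
               for t, g in bundle.truth.marker_catalog.items()],
              outdir / "markers.gmt")
    write_truth(bundle.truth, outdir / "truth.json")
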