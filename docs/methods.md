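# Methods

`scburden` re-implements, as a tested and reusable pipeline, an integrative
analysis that maps genes hit by de novo loss-of-function (LOF) variants in
autism spectrum disorder onto single-cell transcriptomic clusters, scores
those clusters for evolutionary constraint, assigns cell identities from
marker evidence, and characterises developmental expression and
cross-dataset replication. Because the original analysis rests on large
proprietary-scale downloads (brain atlas nuclei, population mutation
databases, developmental bulk RNA-seq), the package ships a synthetic-data
generator that emulates every input with planted ground truth, so each
stage's recovery can be asserted quantitatively.

## The synthetic-data generator (`scburden.synth`)

All generated inputs hang off one `SynthConfig`. A single seed drives
independent per-component random substreams (counts, variants, exons, pLI,
spatiotemporal grid, sorted reference), so adding or regenerating one
component never perturbs another, and identical configs give bit-identical
outputs.

**Counts.** Cells x genes counts are negative binomial with
`var = mu + dispersion * mu^2` (default dispersion 0.5, the usual
overdispersed scRNA-seq regime). Gene baseline relative rates are
log-normal(0, 1); each cell draws an integer library size uniformly from
`library_size_range` (default 5,000–20,000) and gene means scale with it.
Planted marker genes (default 50 per cell type, disjoint blocks) multiply
their rate by `2**marker_log2_effect` (default 2) in their home type, and
their baselines are drawn from a moderately-expressed log-normal stratum
(meanlog 0.5, sdlog 0.5): a marker is by definition an expressed gene, and
a "marker" in the silent tail would be unrecoverable by construction, not
by failure of the method. The closed-form NB moments make the planted
effect analytically checkable. A per-cell mitochondrial fraction is drawn
correlated with library size so the regression step downstream has real
signal to remove. Default sizes (200 neurons, 150 astrocytes,
150 oligodendrocytes; 2,000 genes) keep one full replicate around a second
of CPU while leaving every planted signal identifiable.

**Variants.** The variant table contains exactly the requested count per
(effect, inheritance) category. Default counts are a 1/10-scale version of
the curated landscape's de novo exonic/splicing composition (47 nonsense,
41 frameshift, 20 splicing, 665 missense, ...), dominated — as in real
curations — by noncoding records. Genes for de novo LOF records are drawn
with probability multiplied by `enrichment_multiplier` (default 20) on the
enriched program's markers (default: astrocytes), planting the
cluster-level LOF enrichment the pipeline must find.

**Exons.** Each gene gets 1–20 exons of 1,000–3,000 bp. Baseline exons draw
non-synonymous counts Poisson(0.02/bp x length) and per-stage expression
log-normal(0, 1); planted critical exons draw counts at one quarter of the
baseline rate and expression log-normal(2.5, 0.3) — deep inside the top
expression quartile and the bottom burden quartile, which makes the
quadrant classification identifiable. Note an intrinsic ceiling on
specificity: with 10% of exons planted and a burden threshold at the 25th
percentile of the mixture, about 15% of baseline exons necessarily fall
below the threshold, so chance co-occurrence with top-quartile expression
yields roughly 2.5–3% false flags (specificity ~0.97) even with perfect
separation of the planted stratum.

**pLI.** Exactly `round(frac_high_pli * n_genes)` genes draw pLI from
U(0.95, 1), the rest from U(0, 0.5); the strata are disjoint around the
0.9 cutoff, so the planted set is exactly recoverable. High-pLI genes are
assigned preferentially to the enriched program's markers, coupling the
constraint and LOF signals at the cluster level as the real analysis
observes.

**Spatiotemporal grid.** Genes x (16 regions x 3 periods: prenatal, early
childhood, adult), log-normal base with log-normal(0, 0.3) cell noise.
Genes carrying de novo LOF variants are shifted up by `prenatal_bias_log2`
(default 2) in the prenatal period of the designated regions (defaults:
the DFC and V1C analogues).

**Sorted-cell reference.** Genes x five sorted cell types (neurons first —
the fold-change reference — then astrocytes, oligodendrocytes, microglia,
OPC). The enriched program's markers multiply their astrocyte column by
`sorted_restriction_ratio` (default 8). Per-type noise is log-normal(0,
0.3), so a ratio-8 gene clears the FC > 2 criterion with probability
~0.999. Detection fractions are high (0.8–1.0) for 90% of genes and
sub-threshold for the rest, exercising the 75% detection filter.

**What the generator does not emulate:** donor-level batch structure,
ambient RNA, doublets, chemistry differences, gene–gene correlation beyond
the planted programs, and realistic exon/transcript architecture. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under a clean overdispersed model — not robustness to the
artefacts of real atlas data.

## Preprocessing and clustering (`scburden.scpipe`)

Normalisation is `log2(1 + CPM)`; the pseudocount of 1 on the CPM scale is
this package's choice (the convention states log2 but not the pseudocount).
Highly variable genes (default 2,000) are ranked by standardised variance
under a quadratic log-mean/log-variance trend with z-scores clipped at
sqrt(n_cells); the statistic is computed on the CPM scale (the vst
convention of computing on counts), because log compression hides
high-expression markers. Scaling residualises each gene on cell covariates
(default: percent mitochondrial reads) and z-scores with clipping at ±10
(clip level chosen to prevent outlier dominance; the source convention is
silent). PCA uses a deterministic full SVD with a sign convention (largest
loading positive).

The number of PCs uses an operational elbow rule — the smallest k such
that every subsequent drop in component sd falls below 0.1% of the total
sd, floored at 10 — because "the last PC before the plateau" is not
operational as stated; an explicit override is honoured for parity runs
(the reference analysis used 24/22/24 PCs).

The SNN graph takes each cell's k = 20 nearest neighbours (plus itself) in
PC space; edge weights are the Jaccard overlap of neighbourhoods, pruned
below 1/15 (the originating toolkit's convention) except that every cell
keeps its strongest edge so no node is isolated. Clustering is Leiden on
the weighted SNN graph with the RB-configuration quality function, which
preserves the usual resolution semantics while adding a deterministic
quality guarantee over the original Louvain; labels are relabelled by
decreasing cluster size. tSNE (perplexity 30) is provided for
visualisation only; nothing downstream depends on it.

## Consensus differential expression (`scburden.de`)

One-vs-rest per cluster under four tests:

- **Wilcoxon rank-sum**, two-sided; exact enumeration of midrank
  assignments when both groups have at most 8 cells, tie-corrected normal
  approximation otherwise.
- **Welch's t**, two-sided, with the zero-variance degeneracies defined
  (p = 1 for equal means, 0 otherwise).
- **Bimodal LRT**: a point mass at zero with probability 1 − pi plus a
  normal on positives. The null fits shared (pi, mu, sigma); the
  alternative fits per-group (pi, mu) with shared sigma; all MLEs are
  closed-form, and 2*delta-loglik is referred to chi-square with 2 df
  (1 df when fewer than two positive values exist).
- **Hurdle** (MAST family): a logistic LRT of detection on group (closed
  form for the single binary covariate; complete separation falls back to
  a Haldane-corrected fit and is flagged) plus a Gaussian LRT on the
  positive values; the two chi-square statistics are summed (df = number
  of contributing parts). The cellular-detection-rate covariate is omitted
  by default.

Genes enter testing only if detected in ≥ 10% of in-cluster cells with
|log2 FC| ≥ 0.25 (the toolkit prefilter convention; disableable for oracle
tests). Log2 fold change is computed on the expm CPM scale with
pseudocount 1. Bonferroni uses m = genes tested in that cluster; a
consensus DEG must clear adjusted p < 0.001 in all four tests, and lists
are ordered by decreasing fold change. Benjamini–Hochberg is available for
the pathway stage. DE is one-vs-rest within each matrix (per-region tables
in the real analysis).

## Constraint (`scburden.constraint`)

Exon burden is non-synonymous count / length. An exon is critical at a
stage iff its stage expression reaches the per-stage quantile `q_e`
(default 0.75) and its burden is at or below quantile `q_b` (default
0.25). The reference description ("correlation between mutation burden and
brain expression") gives no formula; this quadrant rule with exposed
quantiles is the package's interpretive choice, applied per stage (whether
the original used per-stage or pooled thresholds is unstated). CE
enrichment of a cluster's DEGs uses the two-sample proportion test
(two-sided, no continuity correction, so that z² equals the Pearson
chi-square exactly — an identity the tests assert); pLI enrichment
(cutoff 0.9) uses Fisher's exact test, with genes missing from the pLI
table excluded from the universe and logged.

## Enrichment engine (`scburden.enrich`)

One-sided hypergeometric upper-tail p (the GeneOverlap convention;
two-sided available), sample odds ratio with Haldane–Anscombe 0.5 applied
only when the OR denominator vanishes and never to the p-value. Batch
enrichment corrects over all cluster x gene-set tests jointly (Bonferroni
default). Pathway enrichment excludes sets strictly below 50 or strictly
above 1000 genes, applies BH across retained sets, and flags significance
at p < 1e-3 and FDR < 0.01. The default universe is all genes present in
the expression matrix (the original's universe is unstated; configurable).

## Annotation (`scburden.annotate`)

Two evidence lines per cluster: the composition of the top-20 consensus
DEGs against the marker catalogue, and the mean normalised marker
expression over the cluster's cells. The call is the composition argmax
iff its fraction reaches tau (default 0.25) and the expression argmax
agrees; ties and disagreements give "unassigned", mirroring the clusters
the visual-inspection analysis left uncalled. Tau is a package choice, not
a reference value; n = 20 follows the donut-plot convention and n = 10 is
supported for the validation-style analyses.

## Spatiotemporal association and replication (`scburden.spatiotemporal`)

Per (region, period) grid cell, expression over the query gene set is
binarised at a within-cell quantile (default the median) and crossed with
variant-gene membership in a 2x2 Fisher test; the odds-ratio construction
is this package's operationalisation (the figure legend defines none), the
quantile is exposed, and variant burden is treated as per-gene binary.
Degenerate (all-equal) cells are flagged rather than tested. The
sorted-cell replication filters genes at detection fraction > 0.75
(interpretation of the "75 percentiles" phrasing; configurable), computes
FC versus neurons with pseudocount 0.01 on the mean-expression scale, and
reports the top 10 genes by maximal non-neuronal FC. `compare_sets`
dispatches to Welch's t (vectors) or Fisher (binarised) so the replication
stage reuses the DE/enrichment primitives.

## Evaluation and problem sizes (`scburden.evaluation`)

A recovery replicate generates a full bundle at the default conditions
(500 cells x 2,000 genes, marker effect 2, multiplier 20, bias 2), runs
clustering → consensus DE → enrichment → annotation → CE → association,
and scores each stage against the planted truth. Recovery runs cluster at
resolution 0.5 — matched to the planted granularity of three broad types,
exactly as resolution is chosen per dataset in real analyses — while 0.8
remains the `cluster()` default. Acceptance-style runs use 10 replicates;
null calibration uses 1,000 NB-simulated null genes at 200 cells per group
and 200 housekeeping-control draws. These sizes were chosen so the whole
evaluation completes in well under a minute per replicate on one CPU while
keeping every binomial check adequately powered.

## Known limitations

- All generator distributions are artifact choices; nothing here is a
  distributional claim about real atlas, mutation-database or
  developmental expression data, and the real-data results (cluster
  counts, specific p-values, gene-level findings) are out of reach at this
  scale by design.
- The bimodal and hurdle models assume normal positives; on log-normalised
  counts this is an approximation that the null-calibration tests bound
  empirically (type-I error within [0.03, 0.07] at alpha 0.05).
- The hurdle covariate path (beyond the group contrast) is minimal; the
  detection-rate covariate of full MAST is not fitted by default.
- Consensus DEG lists keep both up- and down-regulated genes (the
  convention of the underlying toolkit); recovery metrics score positive-FC
  genes against planted markers.
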