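# sistermem

Quantifying **transcriptional memory** across cell divisions: do the two
daughters of one division (sister cells), or the four grand-daughters of
two divisions (cousin cells), keep more similar transcriptomes than
unrelated cells of the same population — and how fast is that similarity
eroded when the cells are induced to differentiate?

`sistermem` is a Python re-implementation of the quantitative framework
behind this question, aimed at computational biologists analyzing
lineage-resolved single-cell expression data (scRT-qPCR ΔCt tables or
scRNA-seq UMI counts) from dye-barcoded sister/cousin isolation
experiments, such as CD34+ hematopoietic progenitors or T2EC erythrocytic
progenitors. Every stage is exercisable end-to-end on a bundled
synthetic-data generator, so the statistical machinery can be validated
without any downloads.

## What it computes

**Lineage inference from fluorescent dye barcodes.** Families of cousin
cells are recovered by model-based Gaussian-mixture clustering of
(log CFSE, log CTY) intensities — six barcodes per plate from three CFSE
levels × CTY on/off — and the two sister pairs inside each 4-cell family
are split on the family median CTFR intensity. Generation-1 sister
identity is validated by the CFSE intensity correlation of true pairs
versus random pairings.

**Preprocessing.** qPCR: instrument-flagged readings are blanked, genes
amplifying in negative-control wells removed, and expression computed as
geomean(Ct_spike1, Ct_spike4) − Ct_gene, floored at −22. RNA-seq: cells
filtered at mean − 3·sd on reads/genes/counts (mean + 3·sd on the ERCC
fraction), orphan cells removed so pairs/quartets stay complete, genes
kept when total UMIs ≥ n_cells, and counts normalized to clipped Pearson
residuals of a regularized negative-binomial regression on log depth and
the experimental covariates (batch, day, medium).

**Distances and resampling nulls.** Manhattan (and Euclidean) distances
within condition, split into sister / cousin / non-related pairs;
Shapiro–Wilk-gated t / Wilcoxon mean comparisons; and a size-matched
subsampling null — 1000 draws of as many non-related distances as there
are sister pairs — with empirical p = (1 + #{null means ≤ observed}) / (B + 1).

**Memory genes.** Per gene, the mixed model

    y = μ + β·condition + b_pair + ε,  b_pair ~ N(0, σ_b²),  ε ~ N(0, σ_e²)

is fit by REML (closed form for the balanced two-cells-per-pair design:
σ̂_e² = MSW, σ̂_b² = max(0, (MSB − MSW)/2) in the no-covariate case) and the
sisterhood random effect is tested with a likelihood-ratio test against the
null model with identical fixed effects, referred to χ²(1). Genes with
Benjamini–Hochberg adjusted p < 0.05 are flagged as memory genes, with
ICC = σ_b²/(σ_b² + σ_e²) as effect size. Negative controls rerun the whole
detection on randomly paired cells.

## Worked example

```python
import sistermem as sm

cfg = sm.SimulationConfig(n_families=30, n_genes=1000, frac_memory=0.1,
                          icc_memory=0.6, seed=1, conditions=("self_renewing",))
ped = sm.simulate_pedigree(cfg)                    # 30 sister pairs
x = sm.simulate_expression(ped, cfg)               # 100 planted memory genes
dm = sm.pairwise_distances(x, metric="manhattan")
sis = sm.mean_distance_by_relation(dm, ped, "sister", "self_renewing")
non = sm.mean_distance_by_relation(dm, ped, "non_related", "self_renewing")
test = sm.compare_means(sis.distances, non.distances)
null = sm.subsample_null(dm, ped, "sister", "self_renewing", B=1000, seed=1)
res = sm.detect_memory_genes(x)
print(f"sister mean Manhattan distance:      {sis.mean:.1f}  (n={sis.n} pairs)")
print(f"non-related mean Manhattan distance: {non.mean:.1f}  (n={non.n} pairs)")
print(f"{test.test}-test p-value:            {test.pvalue:.2e}")
print(f"subsampling-null empirical p:        {null.empirical_p:.4f}")
print(f"memory genes (BH < 0.05):            {int(res['memory'].sum())} of 1000")
```

prints

```
sister mean Manhattan distance:      1089.6  (n=30 pairs)
non-related mean Manhattan distance: 1132.7  (n=1740 pairs)
t-test p-value:            7.15e-12
subsampling-null empirical p:        0.0010
memory genes (BH < 0.05):            82 of 1000
```

Sisters are measurably closer than the 1740 non-related pairs (a ~3.8%
mean-distance reduction driven by the 10% of genes carrying an ICC-0.6
pair effect); the observed sister mean falls below all 1000 size-matched
null means (empirical p = 1/1001); and the gene-wise mixed model recovers
80 of the 100 planted memory genes with 2 false positives.

A command-line interface wraps the same stages
(`sistermem simulate | infer-lineage | preprocess-qpcr | preprocess-rnaseq |
run-qpcr | run-gen2 | run-all`); each workflow writes a report bundle of
CSV/JSON tables (pair counts, distances by relation, null distributions,
memory-gene table) plus optional figures, and identical seeds reproduce
every numeric output byte for byte.

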