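# Methods

This note documents the models behind `sistermem`, the defaults of the
synthetic-data generator, the numerical choices, and what the synthetic
validation does and does not establish about real data.

## The scientific setting

After a cell division the two daughters inherit roughly half of the
mother's content each, and epigenetic and protein-level mechanisms keep
their transcription profiles temporarily aligned — *transcriptional
memory*. Operationally, memory is present when mitotically related cells
(sister pairs after one division, cousin quartets after two) are closer
in expression space than randomly chosen cells of the same population and
condition. A *memory gene* is a gene whose expression varies across
pairs but is correlated within them.

The pipeline has four stages: (1) reconstruct who is related to whom from
heritable fluorescent dye barcodes; (2) turn raw single-cell measurements
(qPCR Ct values or UMI counts) into comparable expression values;
(3) compare distances of related versus non-related pairs with
resampling nulls; (4) detect memory genes gene-by-gene with a mixed
model.

## Lineage inference

Cells are gated CTV-positive first (feeder/decoy cells carry only
autofluorescence; the default gate splits the sorted log-CTV values at
their largest gap and only acts when that gap exceeds one log unit).
Families are recovered per plate group by a full-covariance Gaussian
mixture on (log CFSE, log CTY) — logs because dye dilution is
multiplicative — with 10 restarts. When the component count is not fixed
it is chosen by BIC over `ceil(n_cells/4) .. 6`; the lower bound encodes
that a family holds exactly four cells, and a covariance floor
(`reg_covar = 1e-3`, ≈3% log-intensity spread, the instrument-noise
scale) keeps BIC from overfitting point-like clusters on small plates.
Only families with exactly four recovered cells are retained.

Sister pairs within a family are split at the family median CTFR (mean of
the two middle order statistics): the two cells strictly above form one
pair, the two strictly below the other. Beyond exact ties, a family is
flagged **unresolvable** when the middle gap of the sorted log-CTFR
values does not exceed both (a) the summed within-pair spreads and (b) an
absolute floor of 0.1 log units (10% intensity). Rationale: when the two
inherited CTFR levels collide within measurement noise, the median split
still "succeeds" numerically but pairs arbitrarily; flagging instead of
guessing keeps every resolved pairing trustworthy. Under this rule the
reconstruction is 100% pure (no wrongly merged family, no wrongly matched
pair) over 3×1000 simulated quartets at staining CV ≤ 0.02, at the cost
of leaving ~9% of quartets unresolved. This is the package's documented
operating threshold for barcode identifiability; accuracy degrades
smoothly as staining noise grows.

Sister validation at generation 1 uses the CFSE correlation across
pairs. A correlation over unordered pairs is ill-defined, so both a
canonical ordering (within-pair sort by cell id) and the
both-orderings-averaged symmetric estimate are reported; random pairings
of the same cells give the reference level.

## qPCR preprocessing

Failed readings (instrument QC) become missing and stay missing; genes
amplifying in any water-only negative-control well are removed entirely.
Expression is `geomean(Ct_spike1, Ct_spike4) − Ct_gene`, floored at −22,
the conventional null-signal value of this assay. The geometric mean is
taken of the Ct values themselves (not of 2^−Ct), so nonpositive spike
Cts are rejected; cells whose spike readings failed cannot be normalized
and are dropped with a log entry. Missing values are never imputed —
imputation would inject artificial structure into the sister-similarity
statistics — and propagate to pairwise-complete distance computation
(each pair compared over the genes observed in both cells, with the
per-pair gene count logged).

## RNA-seq preprocessing

Cell filters use `mean − 3·sd` cutoffs on reads, detected genes and total
counts, computed globally over the dataset. The ERCC spike-in fraction is
filtered with an **upper** cutoff `mean + 3·sd`: a high spike fraction
indicates a degraded cell with little endogenous mRNA, so a lower cutoff
would remove exactly the wrong tail. The literal lower-cutoff reading
remains available (`ercc_upper=False`). After cell QC, orphan removal
keeps only complete sister pairs (generation 1) or complete 4-cell
families (generation 2), because every downstream statistic is defined on
complete pairs. Genes are kept when their total UMI count is at least the
number of cells (one UMI per cell on average) — low-count genes have
unusable variance estimates.

Normalization is a contract-level implementation of regularized
negative-binomial Pearson residuals: per gene, a Poisson GLM of counts on
log total depth plus the declared covariates (categorical ones dummy
coded), a moment estimate of the NB dispersion θ, lowess regularization
of log θ against log mean expression across genes, and residuals
`(y − μ)/sqrt(μ + μ²/θ)` clipped at ±sqrt(n_cells). The contract — near
zero mean, unit variance, no linear dependence on depth or the regressed
covariates — is what the test suite asserts; the implementation does not
aim for bit-compatibility with any external tool. Genes whose regression
fails (constant counts, a covariate spanning the gene's entire support)
get zero residuals and a log entry. Sister and cousin datasets are always
processed independently.

## Distances and nulls

Distances are computed within condition only — cross-condition distances
are never pooled. The relation classes sister / cousin / non-related
partition the unordered same-condition pairs (their counts always sum to
n(n−1)/2, which the code asserts). Manhattan distance is the primary
metric (robust to sparsity, and additive over genes, which makes gene-set
restriction exact); Euclidean is kept as a confirmation.

Mean comparisons run Shapiro–Wilk on both samples at α = 0.05; if neither
rejects, a Welch two-sample t-test, otherwise the Wilcoxon rank-sum test.
Constant samples force the rank-sum branch with a warning.

The subsampling null draws B = 1000 subsets of non-related distances,
size-matched to the observed related-pair count, without replacement
within a draw and with replacement across draws; the empirical p-value
for the "related cells are closer" direction uses the (r+1)/(B+1)
estimator, so it is never exactly zero. Gene-set sensitivity repeats the
sister versus non-related comparison over B random gene draws at each
fraction of the panel (10%–90%), BH-adjusting the B p-values within each
fraction.

## The memory-gene model

Per gene, with two observations per sister pair,

    y_cg = μ_g + β_g·1[differentiating] + b_pair(c),g + ε_cg,
    b ~ N(0, σ_b²),  ε ~ N(0, σ_e²).

The condition fixed effect is included whenever two conditions are
present (it must be constant within pairs) and omitted otherwise — the
single-condition variant `y = μ + b + ε`. The response is the *per-cell*
normalized expression: collapsing to per-pair means would make the
random effect unidentifiable from the residual.

Estimation is REML. Transforming each pair to its scaled sum and
difference diagonalizes the covariance (var(sum/√2) = σ_e² + 2σ_b²,
var(diff/√2) = σ_e²), which yields the closed-form solution
σ̂_e² = RSS_diff/q and σ̂_e² + 2σ̂_b² = RSS_sum/(q−p) truncated at the
σ_b² = 0 boundary — identical to the balanced one-way ANOVA estimator
in the no-covariate case, and identical (to optimizer tolerance) to a
general-purpose REML fit, which the tests verify against an independent
mixed-model implementation. Because the solution is closed form, all
genes are fit in one vectorized pass; matrices with missing qPCR readings
fall back to a per-gene complete-pairs loop (genes left with fewer than
three complete pairs are reported as missing, never flagged).

The random effect is tested by a likelihood-ratio test between the full
and null REML fits with identical fixed effects; the statistic is clamped
at zero and referred to χ²(1) by default. This reference is conservative
at the σ_b² = 0 boundary (the asymptotic null is the 50:50 χ²₀/χ²₁
mixture, available via `boundary=True`); the conservative default is kept
because it matches standard practice and type-I control matters more than
a factor of two in power here. Multiple testing uses Benjamini–Hochberg;
"memory gene" means adjusted p below α = 0.05 (configurable — 0.05 is the
conventional choice). The negative control replaces pair labels by a
random perfect matching within condition and reruns the whole detection;
an odd cell count drops one random cell with a warning.

Measured operating characteristics on the generator's default conditions
(computed by the test suite and `scripts/acceptance.py`, not assumed):
type-I after BH ≈ 0 under a global null (50 seeds × 1000 genes); at
ICC 0.6 with 30 pairs, mean recall ≈ 80% of planted genes at FDR ≈ 2%;
ICC recovery error ≤ 0.05 (median) at 500 pairs and ≈ 0.1 at 30 pairs.

## The synthetic-data generator

The generator is first-class, tested code; its defaults *are* the study
conditions under which everything above is validated.

* **Pedigrees**: `n_families` families of one sister pair (generation 1)
  or one 4-cell cousin quartet = two sister pairs (generation 2).
  Families alternate across the configured conditions (self-renewing /
  differentiating) so both media are represented.
* **Expression**: Gaussian on a log scale by default — the analyses run
  on normalized values, and the Gaussian layer keeps the mixed-model
  assumptions exactly satisfiable for parameter-recovery tests. Defaults:
  1000 genes, 10% memory genes, sister ICC 0.6, σ_total = 1, per-gene
  condition effects drawn N(0, 0.5²). On generation-2 pedigrees the
  memory variance splits evenly between a family-level and a pair-level
  component (`family_share = 0.5`), so cousins correlate at half the
  sister ICC. An optional negative-binomial count layer (dispersion 2)
  draws counts with log-mean equal to the latent value.
* **Fluorescence**: barcode = CFSE level (5000/2187/312 a.u., mirroring
  the 5/2.187/0.312 µM staining points) × CTY on/off, unique within a
  plate group of six families; descendant intensity = mother intensity ×
  dilution^divisions × lognormal staining noise. Defaults: dilution 0.5
  per division (equal partitioning; asymmetry is a knob), per-cell
  staining CV 5%, mother-to-mother uptake CV 15%, CTFR heterogeneity
  σ_log = 0.8, background 30 a.u. The dye-noise magnitudes are *choices
  of this package*, not published values: the uptake CV was set so that
  the generation-1 CFSE sister correlation lands near 0.9 (the scale
  reported for real sorts) while adjacent CFSE barcode levels (2.3-fold
  apart) stay separable after two divisions. Feeder cells carry all dyes
  at background and are removed by the CTV gate.
* **Ct tables**: gene Ct = spike geomean − latent expression + N(0,
  0.25²) measurement noise; spikes at Ct 8.0 ± 0.05; configurable
  fractions of failed flags and of spurious negative-control
  amplification. With `base_mean ≈ −17` gene Cts land in the realistic
  mid-20s.
* **Reproducibility**: all outputs derive from one seed through split
  substreams (pedigree / expression / fluorescence / Ct), so requesting
  one output never perturbs another, and identical configs give
  bit-identical outputs.

What the generator does **not** emulate: read-level sequencing noise,
cell-cycle structure, spectral spillover between fluorophores, gene–gene
correlation networks, and zero inflation beyond the NB layer. Passing
tests therefore demonstrate that the *statistical machinery* is correct
and calibrated under its stated assumptions — not that real data satisfy
those assumptions. The real-data benchmark (separate, download-required)
exists for the latter question, and exact reproduction of published gene
lists is not guaranteed because the normalization is contract-level.

## Problem sizes and other numerical choices

The bundled validation runs at the cohort scales of the motivating study
(30–43 sister pairs, 5–8 quartets, 83–1177 genes) and uses B = 1000
subsampling draws where the analysis prescribes them; calibration checks
that need many replicates (null-uniformity of the empirical p, 1000
reconstruction quartets) run at these counts directly because the closed
form REML and vectorized distance code make them cheap. Ambiguity
handling is uniformly "flag, never guess": CTFR ties/near-ties,
unresolvable families, genes with too few complete pairs, and confounded
normalization fits are all reported as such rather than silently
resolved. Tie-breaks that must be deterministic (most-variable-gene
ranking) order by gene id.

## Known limitations

* The LRT reference is conservative at the boundary; with few pairs the
  power cost is visible (recall ~80% at 30 pairs for ICC 0.6).
* The pairwise-complete qPCR distances are not a metric across pairs with
  different gene support; per-pair gene counts are logged so analysts can
  check the support is comparable.
* Lineage recovery (not purity) degrades with staining noise and with
  barcode-level collisions; plates with more than six families are split
  into plate groups by construction.
* The generator's dye-noise defaults are plausibility choices; any claim
  about a specific instrument requires recalibrating them.
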