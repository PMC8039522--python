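# Methods

This note records the statistical models, the defaults and why they are
set where they are, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know about.

## Synthetic-data model

Each planted module m has one latent eigengene E_m with independent
standard-normal values per sample; case samples add the module's disease
effect d_m (log2 units). A member gene with hub weight w_g ∈ (0, 1] is

    x_gs = μ_g + w_g E_ms + sqrt(1 − w_g²) ε_gs,    ε ~ N(0, noise_sd²)

with a per-gene baseline μ_g ~ N(8, 1.5²) mimicking log2 microarray
intensities. Consequences used by the tests: with noise_sd = 1 every gene
has unit variance, cor(x_g, x_h) = w_g w_h within a module, cor(x_g, E_m)
= w_g (the ideal kME), and the expected log2FC of a member gene is w_g d_m.
Background genes are pure noise. Batch effects are additive per gene on
the log2 scale — deliberately the same location/scale family the
empirical-Bayes batch adjuster assumes. Defaults (3 modules × 150 genes,
500 background, 100 samples, hub weights U(0.5, 0.95), case fraction 1/2)
are the desk-scale stand-in for the multi-study microarray cohorts the
pipeline targets.

What the generator does **not** emulate: probe-level chemistry and RNA
degradation (5′/3′ bias enters only as a metadata covariate), correlated
module eigengenes, heavy-tailed expression noise, linkage disequilibrium
between SNPs, and overlapping gene bodies as the rule rather than the
exception. Passing tests therefore certify the machinery under the
latent-factor model, not performance on any particular real cohort.

The GWAS generator draws null SNP p-values uniformly; genes of an enriched
module draw each SNP statistic from a noncentral χ²(1) with noncentrality
`signal_strength · kME_g`, so gene-level −log10 p rises in expectation
with module membership — exactly the signal shape the module × GWAS
Spearman statistic is designed to detect.

## Quality control and normalization

Order: (probe collapse) → log2 → quantile normalization → connectivity
outlier removal → covariate balance check → empirical-Bayes batch
adjustment. Quantile normalization maps each sample's ranks onto the mean
sorted profile; ties receive the mean of their tied target quantiles, which
makes the operation idempotent.

Sample outliers are samples whose network connectivity
k_s = Σ_t cor(x_s, x_t) standardizes below Z < −2; removal iterates
(removing a sample changes the Z distribution) up to 10 rounds and refuses
to empty a diagnosis group. A caveat worth knowing: the minimum of ~n
standardized connectivities falls below −2 with high probability even for
perfectly clean data (an order-statistics fact, not a data defect), so at
the default threshold the iteration will usually trim a few legitimate
samples; `z_threshold` is exposed everywhere and a stricter value (−3)
is used in the bundled example configs where sample economy matters.

The batch adjuster is the standard parametric empirical-Bayes
location/scale algorithm: per gene, fit batch means plus preserved
covariates, standardize by the pooled residual variance, estimate per-batch
location γ and scale δ², shrink them toward method-of-moments normal /
inverse-gamma priors by the usual iterative joint solution (tolerance
1e-5), then remove the shrunken effects and restore the grand fit. It
matches Bioconductor's reference implementation to ~1e-5 on shared
fixtures (a standing test runs that comparison through Rscript).
Degenerate inputs are guarded: a single batch is an identity, a
zero-variance fixture shrinks exactly, priors with zero spread fall back
to unshrunk estimates. Note that EB shrinkage perturbs per-gene grand
means at the order of the shrinkage residue (~1e-4 on typical fixtures);
exact mean preservation is not a property of this algorithm.

Probe collapsing keeps, for each gene, the probe row with the largest mean
across samples (ties to the lexicographically smallest probe ID) — rows
are copies, never averages.

## Differential expression and overlap

The default per-gene model is fixed-effects least squares with two-sided
t-tests; batch enters as a covariate. The opt-in random-intercept variant
profiles the variance ratio λ = σ²_group/σ²_resid out of the Gaussian
likelihood — the marginal covariance is block-diagonal with blocks
I + λJ, whose inverse and determinant are closed-form — and optimizes λ in
1-D (bounded search on the log scale, λ = 0 always a candidate, so a
single group reduces exactly to OLS). Coefficients and log-likelihoods
match statsmodels' MixedLM (ML) to 1e-5; Wald p-values use the normal
approximation conditional on λ̂.

The overlap permutation test permutes gene labels of one log2FC vector;
the add-one estimator keeps p in (0, 1]. Two-sided by default. The
severity slope is principal-axis rather than OLS because both fold-change
vectors carry estimation error; OLS is available behind a flag. Because
estimation noise enters both axes symmetrically, the principal-axis
estimate is consistent when both studies are estimated at similar
precision, but attenuates toward 1 when per-gene noise dominates the
signal variance — visible in the worked example, quantified in the tests.

## Network construction

bicor follows the median/MAD biweight: u = (x − med)/(9·mad), weights
(1 − u²)² inside |u| < 1, correlation of the weighted centered vectors.
Zero-MAD vectors fall back to Pearson with a warning; constant vectors
correlate 0. The matrix version reduces every row to a unit-norm weighted
vector so the all-pairs matrix is one GEMM.

Signed adjacency ((1 + c)/2)^β with β = 9 (default; `pick_soft_threshold`
scans β = 1..20 for the smallest power reaching signed scale-free R² ≥
0.8 and falls back to 9 with a warning). The scale-free statistic bins
connectivities into deciles and regresses log10 density — count/(n·bin
width) — on log10 mean connectivity; R² is signed by −sign(slope) so
decaying laws score positive. Equal-count bins with a density response
were chosen over equal-width histogram counts; for power-law data the two
are equivalent, and the density form has no empty bins.

TOM is the standard formula on the signed adjacency (the (1+c)/2 map
already encodes sign); clustering is average linkage on 1 − TOM via
scipy's nn-chain implementation.

**Tree cut.** The hybrid dynamic tree cut is re-implemented in a
simplified static-height form with the PAM stage off. The deep-split
parameter maps 0..4 → {0.64, 0.73, 0.82, 0.91, 0.95} of the merge-height
range and bounds the search region. Within that region the cut height is
chosen by scanning every possible cut with an incremental union-find,
keeping the plateau of heights that maximize the number of branches with
≥ min_module_size leaves, and placing the cut inside the widest
merge-height gap of that plateau. The gap criterion targets the valley
that separates within-module merges from the dense band of background
attachments near the dendrogram top; the plateau criterion makes module
count non-decreasing in deep_split by construction. On the default
synthetic conditions this recovers planted partitions at adjusted Rand
index 0.99–1.0 with ≥ 99% of background kept grey across seeds. This cut
is this package's own design; it does not claim equality with any
reference implementation of dynamic tree cutting.

Eigengenes are first principal components of the z-scored member
submatrix (unit variance, ddof 1), sign-oriented so the mean member
correlation is positive. kME is Pearson by default (bicor behind a flag).
Merging dissolves the closest eigengene pair while 1 − cor < 0.1,
recomputing after every merge; final modules are renamed by size down the
standard color palette (largest = turquoise), which keeps labels
deterministic.

Robustness: module detection is repeated on n_resamples (default 100)
subsets of ⌈2n/3⌉ samples drawn without replacement from a seeded
generator. A gene's stability is the fraction of resamples in which it
lands in the same resample-module as the majority of its full-data module;
genes below 0.5 are re-assigned grey. The 0.5 threshold and the
majority-label matching rule are this package's concretization of
consensus analysis.

## Module-level statistics

Module–trait association regresses each eigengene on the trait plus
covariates (diagnosis coded control = 0 / case = 1, so positive β =
up-regulated in disease), with a random intercept per study when several
studies are combined, and BH FDR over all module × trait tests in one
family. Covariate screens are plain per-module linear regressions with R²
reported.

The specificity index of gene g for cell type c is the mean over other
cell types c′ of g's rank by descending expression ratio
(x_gc + 1)/(x_gc′ + 1) (rank 1 = most specific; the +1 guards zeros; log2
mean-collapsed replicate references are the expected input). Its p-value
is empirical against a null that permutes every gene's values across cell
types and **pools all genes' null SIs per cell type** — a per-gene null
would leave a marker maximally specific in a random cell type and could
never reject; the pooled form is calibrated (measured type-I error 0.050
at the 0.05 level) and gives markers p ≈ 1/n_genes. Cell-type sets are
genes with pSI < 0.05; module enrichment in them is one-sided Fisher with
Haldane-corrected odds ratios; pathway over-representation is the
hypergeometric upper tail over sets filtered to 10–2,000 genes after
background intersection (bounds inclusive). The background defaults to
the network's gene universe.

## GWAS enrichment

SNPs map to every gene whose (1-based, inclusive) start−window..stop+window
interval contains them; BED input is converted from 0-based half-open on
read. The gene statistic is the Šidák-corrected minimum,
p_gene = 1 − (1 − min p)^n_snps, computed via log1p/expm1 for precision —
exactly uniform under independent uniform SNP p-values, and a deliberate
independent-SNP simplification: LD-aware gene statistics are out of scope,
and externally computed gene-level p-values can be supplied instead.
Enrichment per module × GWAS is Spearman's ρ between all genes' kME to
that module and their −log10 gene p, one-sided for ρ > 0 by default
(risk-signal enrichment), BH-corrected across all module × GWAS cells.

## Pipeline and determinism

`run_all` executes QC → DGE/overlap → network → association → enrichment
→ GWAS. Datasets are combined for network construction only when their
overlap permutation p falls below the configurable gate (default 0.05);
combined sets are re-adjusted with dataset-as-batch empirical Bayes,
preserving diagnosis. One global seed spawns per-stage seeds through
numpy's SeedSequence (children reduced mod 2³¹), so stage reruns and full
reruns are reproducible; all tables are written with a fixed float format,
making identical runs byte-identical.

## Problem sizes in the test suite

Unit and acceptance tests run at desk scale, chosen to make every
stochastic assertion decisive at the 99% binomial confidence level while
keeping the whole suite in a couple of minutes: 950–2,000 genes, 40–100
samples, 100–1,000 permutations or replicates per calibration, 3–20
network resamples. The acceptance script uses the same conditions.

## Known limitations

- The tree cut assumes a dendrogram whose background attachments sit above
  module merges; data without that separation (e.g., one giant diffuse
  module) will fold background into modules, which the resampling
  consensus only partly repairs.
- Connectivity-based outlier removal at Z < −2 trims clean data too (see
  above); treat the QC report as an audit log, not an oracle.
- The mixed-model Wald p-values ignore uncertainty in the variance ratio;
  at very small group counts they are mildly anti-conservative.
- No block-wise network path: gene universes beyond ~30k genes will not
  fit the dense bicor/TOM matrices this implementation uses.
- pSI p-values inherit permutation granularity (resolution 1/(B·n_genes));
  with few genes, raise n_permutations.
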