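# nephronet

Cross-disease transcriptome comparison for case/control expression cohorts,
built around a from-scratch signed weighted gene co-expression network.
The package grew out of the question of how much two immune-mediated kidney
diseases (IgA nephropathy and lupus nephritis) share at the level of renal
gene expression: do their differential-expression signatures overlap, how
strong is each perturbation relative to the other, which co-expression
modules track disease, which kidney cell types and pathways do those
modules point at, and do GWAS risk signals concentrate on module hubs?

All of those questions are answered by generic machinery that works on any
gene × sample expression matrix with case/control metadata — the kidney
application is just the motivating instance.

## What it computes

**Differential-expression overlap.** Per-gene log2 fold changes come from
linear models (`expression ~ diagnosis + covariates`, optionally with a
random intercept per batch fit by profiled maximum likelihood). For two
studies A and B the overlap is Spearman's ρ of their log2FC vectors over
the shared genes, with significance from a gene-permutation null
(p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (B + 1)). The severity gradient between
studies is the principal-axis (total least squares) slope
sign(cov)·√(var_B/var_A): a slope above 1 means B perturbs the shared
transcriptome more strongly than A.

**Signed co-expression network.** Gene–gene similarity is the biweight
midcorrelation (bicor); the signed adjacency is a_ij = ((1 + c_ij)/2)^β
with β = 9 chosen against the scale-free topology criterion (signed
R² > 0.8); genes are clustered by average linkage on the topological
overlap dissimilarity 1 − TOM; modules are branches of that dendrogram
(minimum size 100, deepSplit 3, PAM off), merged when their eigengenes
correlate above 0.9; every gene gets a module membership kME = cor(gene,
eigengene); and module robustness is scored by re-detecting modules on
100 resamples of 2/3 of the samples, sending unstable genes to grey.

**Module-level biology.** Module eigengenes (first principal components)
are regressed on disease status and nuisance covariates (RIN, 5′/3′ bias)
with Benjamini–Hochberg FDR across all module × trait tests; cell-type
specificity uses the specificity index (mean cross-cell-type expression
ratio rank) with a permutation null (pSI < 0.05 sets, Fisher's exact
enrichment); pathways use hypergeometric over-representation against GMT
collections filtered to 10–2,000 genes; and GWAS enrichment per module is
the Spearman correlation between every gene's kME and its gene-level
−log10 p (Šidák-corrected minimum SNP p over the gene body, or externally
computed gene statistics).

**Synthetic data with known truth.** A latent-factor generator plants
co-expression modules (gene g in module m: x = w_g·E_m + √(1−w_g²)·ε, so
kME_g → w_g), disease shifts on eigengenes (per-gene log2FC = w_g·d),
batch offsets, probe tables, purified cell-type references with markers,
and GWAS summary statistics whose signal grows with kME. Every analysis
stage is therefore testable against ground truth at desk scale.

## Worked example

`examples/03_coexpression_modules.py` plants three 150-gene modules among
500 background genes (100 samples), runs the full network stack with 20×
resampling consensus, and compares against the planted truth:

```
modules found: 3 (sizes [151, 148, 143])
adjusted Rand index vs planted partition: 0.997
background genes kept grey: 0.998
top hub genes of the largest module (gene, kME):
  G00069  0.966
  G00115  0.955
  G00067  0.950
  G00101  0.947
  G00083  0.941
```

An adjusted Rand index of 0.997 means the recovered partition is nearly
identical to the planted one; the hub kME values approach the planted
loadings w_g. The other examples cover QC/normalization (01), DGE overlap
and severity slopes (02), module–trait association (04), cell-type and
pathway enrichment (05), GWAS enrichment (06) and the config-driven
end-to-end pipeline (07); each prints the numbers it computes and one line
on how to read them.

There is also a thin CLI over the same functions:

```bash
nephronet simulate --outdir sim --seed 1
nephronet network sim/expression.tsv --resamples 20 --outdir net
nephronet run-all config.yaml
```

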