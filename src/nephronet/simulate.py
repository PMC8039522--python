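"""Synthetic multi-study expression data with known ground truth.

The generator follows a single-latent-factor model per co-expression module:
every planted module m has one latent eigengene E_m (standard normal across
samples, shifted by the planted disease effect in cases), and a member gene g
with hub weight w_g in (0, 1] is

    x_gs = mu_g + w_g * E_ms + sqrt(1 - w_g^2) * eps,   eps ~ N(0, noise_sd^2)

so with noise_sd = 1 every gene has unit variance, the expected Pearson
correlation of two members is w_g * w_h, the gene's correlation with the
latent factor (its ideal kME) is w_g, and a disease shift d on E_m induces an
expected per-gene log2 fold change of w_g * d. Background genes are pure
noise and carry the "grey" label. Batch effects are additive per gene on the
log2 scale, matching the location/scale model the batch adjuster assumes.

Companion generators produce probe-level tables (for max-mean collapsing),
replicate-level cell-type references with planted markers, gene annotations,
GWAS summary statistics with kME-proportional signal, and toy gene-set
collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GREY = "grey"

#: deterministic module colour palette, assigned largest module first
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


@dataclass
class SyntheticTruth:
    """Ground-truth record for recovery tests."""

    module_assignment: pd.Series          # gene -> module label ("grey" = none)
    hub_weights: pd.Series                # gene -> w_g in (0, 1]
    disease_effects: dict                 # module -> eigengene shift (log2 units)
    batch_offsets: pd.DataFrame | None    # gene x batch additive shifts
    marker_map: dict = field(default_factory=dict)   # cell type -> marker genes
    gwas_enriched_module: str | None = None
    seed: int = 0
    latent_factors: pd.DataFrame | None = None       # module x sample E_ms


@dataclass
class SyntheticBundle:
    expression: pd.DataFrame   # gene x sample, log2 scale
    metadata: pd.DataFrame     # indexed by sample_id
    truth: SyntheticTruth


def simulate_expression_study(
    n_genes: int = 950,
    n_samples: int = 100,
    module_sizes=(150, 150, 150),
    hub_weight_range=(0.5, 0.95),
    case_fraction: float = 0.5,
    disease_effect=None,
    batch_plan=None,
    batch_offset_sd: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    study: str = "study1",
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> SyntheticBundle:
    """Simulate one case/control expression study with planted modules.

    ``disease_effect`` maps module label -> eigengene shift in cases (log2
    units); unlisted modules get 0. ``batch_plan`` is a sequence of batch
    labels, one per sample (default: a single batch); per-gene batch offsets
    are drawn N(0, batch_offset_sd^2). Nuisance covariates ``rin`` and
    ``bias_53`` are drawn independently of diagnosis.
    """
    module_sizes = list(module_sizes)
    if any(s <= 0 for s in module_sizes):
        raise ValueError("module sizes must be positive")
    if sum(module_sizes) > n_genes:
        raise ValueError(
            f"module sizes sum to {sum(module_sizes)} > n_genes={n_genes}")
    if not 0.0 < case_fraction < 1.0:
        raise ValueError("case_fraction must be in (0, 1)")
    lo, hi = hub_weight_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("hub weights must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"{study}_S{j:03d}" for j in range(n_samples)]
    labels = [MODULE_COLORS[i] for i in range(len(module_sizes))]

    n_cases = int(round(case_fraction * n_samples))
    diagnosis = np.array(["control"] * n_samples)
    diagnosis[rng.choice(n_samples, size=n_cases, replace=False)] = "case"
    is_case = (diagnosis == "case").astype(float)

    effects = {m: 0.0 for m in labels}
    if disease_effect:
        unknown = set(disease_effect) - set(labels)
        if unknown:
            raise ValueError(f"disease_effect for unknown modules: {sorted(unknown)}")
        effects.update(disease_effect)

    assignment = pd.Series(GREY, index=genes, name="module")
    weights = pd.Series(0.0, index=genes, name="hub_weight")
    X = np.empty((n_genes, n_samples))
    latent = pd.DataFrame(index=labels, columns=samples, dtype=float)

    start = 0
    for m, size in zip(labels, module_sizes):
        E = rng.standard_normal(n_samples) + effects[m] * is_case
        latent.loc[m] = E
        idx = slice(start, start + size)
        w = rng.uniform(lo, hi, size=size)
        eps = rng.standard_normal((size, n_samples)) * noise_sd
        X[idx] = w[:, None] * E[None, :] + np.sqrt(1.0 - w**2)[:, None] * eps
        assignment.iloc[idx] = m
        weights.iloc[idx] = w
        start += size
    X[start:] = rng.standard_normal((n_genes - start, n_samples)) * noise_sd

    mu = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    X += mu[:, None]

    if batch_plan is None:
        batch = np.array(["b1"] * n_samples)
    else:
        batch = np.asarray(batch_plan)
        if batch.shape[0] != n_samples:
            raise ValueError("batch_plan length must equal n_samples")
    batch_levels = sorted(pd.unique(batch))
    offsets = None
    if batch_offset_sd > 0 and len(batch_levels) > 1:
        offsets = pd.DataFrame(
            rng.normal(0.0, batch_offset_sd, size=(n_genes, len(batch_levels))),
            index=genes, columns=batch_levels)
        for b in batch_levels:
            X[:, batch == b] += offsets[b].to_numpy()[:, None]

    expression = pd.DataFrame(X, index=pd.Index(genes, name="gene"),
                              columns=samples)
    metadata = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "batch": batch,
            "study": study,
            "rin": np.round(rng.uniform(6.0, 10.0, size=n_samples), 2),
            "bias_53": np.round(rng.normal(1.5, 0.25, size=n_samples), 3),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = SyntheticTruth(
        module_assignment=assignment, hub_weights=weights,
        disease_effects=effects, batch_offsets=offsets,
        seed=seed, latent_factors=latent)
    return SyntheticBundle(expression=expression, metadata=metadata, truth=truth)


def simulate_probe_table(gene_matrix: pd.DataFrame, probes_per_gene: int = 2,
                         probe_noise_sd: float = 0.1, seed: int = 0):
    """Expand a gene matrix to probe level (gene profile + shift + noise).

    Returns ``(probe_matrix, probe_map)`` where the map has columns
    ``probe_id`` and ``gene_id``. With one probe per gene and zero noise,
    collapsing the probe table recovers the input exactly.
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    rows, probe_ids, gene_ids = [], [], []
    values = gene_matrix.to_numpy()
    for i, gene in enumerate(gene_matrix.index):
        for j in range(probes_per_gene):
            shift = 0.0 if probes_per_gene == 1 else rng.normal(0.0, 1.0)
            noise = rng.normal(0.0, probe_noise_sd, size=values.shape[1]) \
                if probe_noise_sd > 0 else 0.0
            rows.append(values[i] + shift + noise)
            probe_ids.append(f"{gene}_p{j}")
            gene_ids.append(gene)
    probe_matrix = pd.DataFrame(np.asarray(rows),
                                index=pd.Index(probe_ids, name="probe_id"),
                                columns=gene_matrix.columns)
    probe_map = pd.DataFrame({"probe_id": probe_ids, "gene_id": gene_ids})
    return probe_matrix, probe_map


def simulate_cell_reference(n_genes: int = 500, cell_types=("mesangial",
                            "glom_epithelial", "tubule_epithelial", "podocyte"),
                            markers_per_type: int = 25, fold_change: float = 16.0,
                            replicates: int = 3, noise_sd: float = 0.2,
                            seed: int = 0):
    """Replicate-level cell-type reference (raw FPKM-like scale).

    Marker genes are elevated ``fold_change``-fold in their own cell type;
    replicates get multiplicative lognormal noise. Returns ``(reference,
    marker_map)`` with columns named ``{cell_type}_rep{k}``.
    """
    cell_types = list(cell_types)
    if fold_change <= 1:
        raise ValueError("fold_change must exceed 1")
    if markers_per_type * len(cell_types) > n_genes:
        raise ValueError("more markers requested than genes available")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n_genes)
    marker_map: dict[str, list[str]] = {}
    mean = np.tile(base[:, None], (1, len(cell_types)))
    cursor = 0
    for c, ct in enumerate(cell_types):
        idx = range(cursor, cursor + markers_per_type)
        marker_map[ct] = [genes[i] for i in idx]
        mean[list(idx), c] *= fold_change
        cursor += markers_per_type
    cols, data = [], []
    for c, ct in enumerate(cell_types):
        for r in range(replicates):
            cols.append(f"{ct}_rep{r + 1}")
            noise = rng.lognormal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else 1.0
            data.append(mean[:, c] * noise)
    reference = pd.DataFrame(np.column_stack(data),
                             index=pd.Index(genes, name="gene"), columns=cols)
    return reference, marker_map


def make_gene_annotation(gene_ids, n_chromosomes: int = 4,
                         gene_length: int = 10_000, gap: int = 5_000) -> pd.DataFrame:
    """Deterministic non-overlapping gene annotation (1-based inclusive)."""
    rows = []
    per_chrom = int(np.ceil(len(gene_ids) / n_chromosomes))
    for i, g in enumerate(gene_ids):
        chrom = f"chr{i // per_chrom + 1}"
        pos_in_chrom = i % per_chrom
        start = 1 + pos_in_chrom * (gene_length + gap)
        rows.append((g, chrom, start, start + gene_length - 1))
    return pd.DataFrame(rows, columns=["gene", "chr", "start", "stop"])


def simulate_gwas(gene_annotation: pd.DataFrame, snps_per_gene: int = 5,
                  kme: pd.Series | None = None,
                  truth: SyntheticTruth | None = None,
                  enriched_module: str | None = None,
                  signal_strength: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Simulate GWAS summary statistics (snp, chr, bp, p); SNPs independent.

    Null genes get p ~ Uniform(0,1). Genes of ``enriched_module`` draw each
    SNP's test statistic from a noncentral chi-square(1) with noncentrality
    ``signal_strength * kME_g`` (kME taken from the supplied kME column or,
    failing that, the truth's hub weights), so gene-level -log10 p rises in
    expectation with module membership.
    """
    rng = np.random.default_rng(seed)
    member = pd.Series(False, index=gene_annotation["gene"])
    kme_vals = pd.Series(0.0, index=gene_annotation["gene"])
    if enriched_module is not None:
        if truth is not None:
            members = truth.module_assignment[
                truth.module_assignment == enriched_module].index
            if len(members) == 0:
                raise ValueError(f"module {enriched_module!r} not in truth")
            weights = truth.hub_weights
        elif kme is not None:
            members = kme.index
            weights = kme.clip(lower=0.0)
        else:
            raise ValueError("enriched_module requires kme or truth")
        common = member.index.intersection(members)
        if len(common) == 0:
            raise ValueError(f"module {enriched_module!r} has no annotated genes")
        member.loc[common] = True
        kme_vals.loc[common] = weights.reindex(common).fillna(0.0)

    rows = []
    for _, rec in gene_annotation.iterrows():
        g, chrom, start, stop = rec["gene"], rec["chr"], int(rec["start"]), int(rec["stop"])
        if stop < start:
            raise ValueError(f"gene {g} has start > stop")
        bps = np.sort(rng.integers(start, stop + 1, size=snps_per_gene))
        if member.loc[g] and signal_strength > 0:
            nc = signal_strength * float(kme_vals.loc[g])
            stat = rng.noncentral_chisquare(df=1, nonc=max(nc, 1e-12),
                                            size=snps_per_gene)
            from scipy.stats import chi2
            p = chi2.sf(stat, df=1)
        else:
            p = rng.uniform(0.0, 1.0, size=snps_per_gene)
        for k in range(snps_per_gene):
            rows.append((f"{g}_snp{k}", chrom, int(bps[k]),
                         float(np.clip(p[k], np.finfo(float).tiny, 1.0))))
    return pd.DataFrame(rows, columns=["snp", "chr", "bp", "p"])


def simulate_gene_sets(gene_ids, n_sets: int = 20, size_range=(10, 200),
                       planted_subset=None, planted_name: str = "planted_pathway",
                       seed: int = 0) -> dict:
    """Toy gene-set collection; optionally includes one set drawn from a
    planted module so over-representation has a known positive."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        sets[f"SET{i:03d}"] = sorted(members.tolist())
    if planted_subset is not None:
        sets[planted_name] = sorted(planted_subset)
    return sets
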