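"""GWAS-signal enrichment per co-expression module.

SNPs are mapped to genes by position (1-based inclusive start-stop, optional
window), aggregated to a gene-level p-value with the Sidak-corrected minimum
(an independent-SNP stand-in for LD-aware gene statistics; externally
computed gene-level p-values can be supplied instead), and each module's
enrichment is the Spearman correlation between every gene's kME to that
module and its gene-level -log10 p, one-sided for positive rho, BH-corrected
across all module x GWAS combinations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import bh_fdr, spearman_onesided


def _validate_snps(snps: pd.DataFrame) -> pd.DataFrame:
    for col in ("snp", "chr", "bp", "p"):
        if col not in snps.columns:
            raise ValueError(f"SNP table lacks column {col!r}")
    bp = pd.to_numeric(snps["bp"], errors="coerce")
    bad = snps.index[bp.isna() | (bp <= 0) | (bp != bp.round())]
    if len(bad):
        raise ValueError(f"malformed SNP position at line {int(bad[0]) + 1}")
    return snps.assign(bp=bp.astype(int))


def map_snps_to_genes(snps: pd.DataFrame, annotation: pd.DataFrame,
                      window: int = 0) -> dict:
    """Gene -> sub-table of SNPs inside [start - window, stop + window].

    A SNP may map to several overlapping genes; unmapped SNPs are dropped
    (count reported via a warning).
    """
    snps = _validate_snps(snps)
    if (annotation["start"] > annotation["stop"]).any():
        raise ValueError("annotation has start > stop")
    mapping: dict[str, pd.DataFrame] = {}
    mapped_idx: set[int] = set()
    by_chrom = {c: t.sort_values("bp") for c, t in snps.groupby("chr")}
    for _, rec in annotation.iterrows():
        chrom = rec["chr"]
        if chrom not in by_chrom:
            continue
        t = by_chrom[chrom]
        lo = int(rec["start"]) - window
        hi = int(rec["stop"]) + window
        left = t["bp"].searchsorted(lo, side="left")
        right = t["bp"].searchsorted(hi, side="right")
        if right > left:
            hit = t.iloc[left:right]
            mapping[rec["gene"]] = hit
            mapped_idx.update(hit.index)
    n_unmapped = len(snps) - len(mapped_idx)
    if n_unmapped:
        warnings.warn(f"{n_unmapped} SNP(s) mapped to no gene and were dropped")
    return mapping


def gene_level_p(mapping: dict) -> pd.DataFrame:
    """Sidak-corrected minimum SNP p per gene: 1 - (1 - min p)^n_snps."""
    rows = []
    for gene in sorted(mapping):
        t = mapping[gene]
        p = t["p"].to_numpy(dtype=float)
        if np.any(p <= 0):
            warnings.warn(f"gene {gene}: p = 0 clamped to machine minimum")
            p = np.clip(p, np.finfo(float).tiny, None)
        if np.any(p > 1):
            raise ValueError(f"gene {gene}: SNP p > 1")
        n = len(p)
        rows.append({"gene": gene, "n_snps": n,
                     "p": float(-np.expm1(n * np.log1p(-np.min(p))))
                     if np.min(p) < 1 else 1.0,
                     "source": "computed"})
    out = pd.DataFrame(rows).set_index("gene")
    out["p"] = out["p"].clip(np.finfo(float).tiny, 1.0)
    return out


def load_gene_level_stats(path) -> pd.DataFrame:
    """Read externally computed gene-level p-values (columns: gene, p)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "p"}.issubset(df.columns):
        raise ValueError("expected columns 'gene' and 'p'")
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene {dup.iloc[0]!r}")
    p = df["p"].astype(float)
    if ((p <= 0) | (p > 1)).any():
        bad = df["gene"][(p <= 0) | (p > 1)].iloc[0]
        raise ValueError(f"gene {bad!r} has p outside (0, 1]")
    out = df.set_index("gene")[["p"]]
    out["n_snps"] = 0
    out["source"] = "supplied"
    return out[["n_snps", "p", "source"]]


def module_gwas_enrichment(kme_matrix: pd.DataFrame, gene_stats: dict,
                           alternative: str = "greater") -> pd.DataFrame:
    """Spearman(kME, -log10 gene p) per module x GWAS, FDR over all cells.

    kME columns are modules; every gene's membership to every module is
    used, not just assigned members.
    """
    rows = []
    for gwas_name in sorted(gene_stats):
        stats_df = gene_stats[gwas_name]
        shared = kme_matrix.index.intersection(stats_df.index)
        if len(shared) < 30:
            raise ValueError(
                f"GWAS {gwas_name!r}: only {len(shared)} shared genes (< 30)")
        neglog = -np.log10(stats_df.loc[shared, "p"].to_numpy(dtype=float))
        for module in kme_matrix.columns:
            rho, p = spearman_onesided(
                kme_matrix.loc[shared, module].to_numpy(), neglog,
                alternative=alternative)
            rows.append({"module": module, "gwas": gwas_name, "rho": rho,
                         "p": p, "n_genes": len(shared)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["module", "gwas", "rho", "p", "q", "n_genes"]]
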