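"""Cell-type specificity enrichment and gene-set over-representation.

The specificity index (SI) of gene g for cell type c is the mean, over all
other cell types c', of g's rank when genes are ordered by descending
expression ratio x_gc / x_gc' (rank 1 = most c-specific). Its significance
comes from a permutation null that shuffles each gene's expression across
cell types. Genes below the pSI threshold form a cell type's specific set,
and module membership in those sets is tested with a one-sided Fisher's
exact test over the expression background, BH-corrected. Generic gene-set
over-representation works the same way against a user-supplied GMT
collection with a 10-2000 set-size filter.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_fdr

#: pseudo-expression added before ratios so zeros cannot divide
EPSILON = 1.0


def collapse_reference(replicate_matrix: pd.DataFrame,
                       mapping: dict | None = None,
                       log2: bool = True) -> pd.DataFrame:
    """Average replicate columns per cell type (log2(x+1) first by default).

    Without an explicit mapping, column names ``{cell_type}_rep{k}`` are
    parsed.
    """
    if mapping is None:
        mapping = {}
        for col in replicate_matrix.columns:
            m = re.match(r"(.+)_rep\d+$", col)
            if not m:
                raise ValueError(f"cannot parse cell type from column {col!r}")
            mapping.setdefault(m.group(1), []).append(col)
    vals = replicate_matrix.astype(float)
    if log2:
        if (vals.to_numpy() < 0).any():
            raise ValueError("negative expression in reference")
        vals = np.log2(vals + 1.0)
    out = pd.DataFrame({ct: vals[cols].mean(axis=1)
                        for ct, cols in mapping.items()})
    if out.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    return out


def _si_from_values(vals: np.ndarray) -> np.ndarray:
    """SI matrix (genes x cell types) from a reference value matrix."""
    n_genes, n_types = vals.shape
    shifted = vals + EPSILON
    si = np.zeros((n_genes, n_types))
    for c in range(n_types):
        ranks_sum = np.zeros(n_genes)
        for c2 in range(n_types):
            if c2 == c:
                continue
            ratio = shifted[:, c] / shifted[:, c2]
            # descending ranks, ties averaged
            ranks_sum += stats.rankdata(-ratio, method="average")
        si[:, c] = ranks_sum / (n_types - 1)
    return si


def specificity_index(reference: pd.DataFrame) -> pd.DataFrame:
    """Mean cross-cell-type specificity rank per gene (1 = most specific)."""
    if reference.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if reference.shape[0] < 20:
        raise ValueError("need at least 20 genes for meaningful ranks")
    si = _si_from_values(reference.to_numpy(dtype=float))
    return pd.DataFrame(si, index=reference.index, columns=reference.columns)


def psi_pvalue(reference: pd.DataFrame, n_permutations: int = 1000,
               seed: int = 0) -> pd.DataFrame:
    """Empirical p-value of each gene's SI per cell type.

    Null: permute every gene's expression across cell types independently
    and recompute SI; the null SI distribution for a cell type pools all
    genes across permutations (a gene compared only to permutations of
    itself would stay "specific" under the null). Add-one estimator:
    p = (1 + #{SI_null <= SI_obs}) / (B * n_genes + 1), never exactly zero.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    vals = reference.to_numpy(dtype=float)
    si_obs = _si_from_values(vals)
    rng = np.random.default_rng(seed)
    n_genes, n_types = vals.shape
    counts = np.zeros_like(si_obs)
    for _ in range(n_permutations):
        perm = rng.permuted(vals, axis=1)
        si_null = _si_from_values(perm)
        for c in range(n_types):
            null_sorted = np.sort(si_null[:, c])
            counts[:, c] += np.searchsorted(null_sorted, si_obs[:, c],
                                            side="right")
    p = (1.0 + counts) / (n_permutations * n_genes + 1.0)
    return pd.DataFrame(p, index=reference.index, columns=reference.columns)


def celltype_specific_sets(p_table: pd.DataFrame,
                           psi_threshold: float = 0.05) -> dict:
    """Cell type -> genes with pSI below the threshold."""
    return {ct: sorted(p_table.index[p_table[ct] < psi_threshold])
            for ct in p_table.columns}


def _fisher_rows(module_genes, sets: dict, background) -> pd.DataFrame:
    bg = set(background)
    mod = set(module_genes) & bg
    rows = []
    for name, genes in sets.items():
        s = set(genes) & bg
        overlap = mod & s
        a = len(overlap)
        b = len(mod) - a
        c = len(s) - a
        d = len(bg) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append({"set": name, "overlap": a, "set_size": len(s),
                     "module_size": len(mod), "background": len(bg),
                     "odds_ratio": float(odds), "p": float(p),
                     "genes": ",".join(sorted(overlap))})
    return pd.DataFrame(rows)


def fisher_enrichment(module_sets: dict, celltype_sets: dict,
                      background) -> pd.DataFrame:
    """One-sided Fisher enrichment of each module in each cell-type set.

    ``module_sets`` maps module label -> member genes. BH FDR spans all
    module x set tests.
    """
    if len(background) == 0:
        raise ValueError("empty background")
    frames = []
    for module, genes in module_sets.items():
        df = _fisher_rows(genes, celltype_sets, background)
        df.insert(0, "module", module)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def ora_genesets(module_genes, collection: dict, background,
                 min_size: int = 10, max_size: int = 2000) -> pd.DataFrame:
    """Hypergeometric over-representation of one module in a GMT collection.

    Sets are intersected with the background first; those outside
    [min_size, max_size] (inclusive) are dropped. BH FDR within the tested
    sets.
    """
    bg = set(background)
    mod = set(module_genes) & bg
    kept = {}
    for name, genes in collection.items():
        s = set(genes) & bg
        if min_size <= len(s) <= max_size:
            kept[name] = s
    if not kept:
        warnings.warn("all gene sets removed by the size filter")
        return pd.DataFrame(columns=["set", "overlap", "set_size",
                                     "module_size", "p", "q", "genes"])
    N, n = len(bg), len(mod)
    rows = []
    for name in sorted(kept):
        s = kept[name]
        k = len(mod & s)
        p = float(stats.hypergeom.sf(k - 1, N, len(s), n))
        rows.append({"set": name, "overlap": k, "set_size": len(s),
                     "module_size": n, "p": p,
                     "genes": ",".join(sorted(mod & s))})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
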