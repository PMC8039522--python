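"""Per-gene differential expression, cross-disease overlap, severity slopes.

log2FC is the case-minus-control coefficient of a per-gene linear model
(expression ~ diagnosis + covariates). The cross-disease overlap statistic is
the Spearman correlation of two studies' log2FC vectors over their shared
genes, with significance from a gene-label permutation null. The severity
slope is the principal-axis (total least squares) regression slope of one
study's log2FC on another's, so a slope above 1 means the target disease
perturbs the shared transcriptome more strongly than the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import (bh_fdr, fit_random_intercept, ols_fit,
                    permutation_spearman)


@dataclass
class OverlapResult:
    pair: tuple
    rho: float
    p: float
    n_genes: int
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "rho": self.rho, "p": self.p,
                "n_genes": self.n_genes,
                "n_permutations": self.n_permutations, "seed": self.seed}


@dataclass
class SlopeResult:
    reference: str
    target: str
    slope: float
    method: str
    n_genes: int

    def to_dict(self) -> dict:
        return {"reference": self.reference, "target": self.target,
                "slope": self.slope, "method": self.method,
                "n_genes": self.n_genes}


def _design(metadata: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(metadata))]
    names = ["intercept"]
    diag = (metadata["diagnosis"] == "case").astype(float)
    cols.append(diag.to_numpy())
    names.append("diagnosis")
    for c in covariates:
        x = metadata[c]
        if pd.api.types.is_numeric_dtype(x):
            cols.append(x.astype(float).to_numpy())
            names.append(c)
        else:
            d = pd.get_dummies(x, drop_first=True, dtype=float)
            for lvl in d.columns:
                cols.append(d[lvl].to_numpy())
                names.append(f"{c}[{lvl}]")
    return np.column_stack(cols), names


def fit_dge(matrix: pd.DataFrame, metadata: pd.DataFrame, covariates=(),
            random_intercept: str | None = None,
            dataset_id: str = "") -> pd.DataFrame:
    """Per-gene case-vs-control effects with BH FDR.

    Default: fixed-effects least squares with two-sided t p-values. With
    ``random_intercept`` naming a grouping column (and >1 group), each gene
    is fit by profiled maximum likelihood with a random intercept per group
    and Wald p-values.
    """
    meta = metadata.loc[matrix.columns]
    counts = meta["diagnosis"].value_counts()
    if counts.get("case", 0) < 3 or counts.get("control", 0) < 3:
        raise ValueError("need at least 3 samples in each diagnosis group")
    X, names = _design(meta, covariates)
    Y = matrix.to_numpy(dtype=float)
    j = names.index("diagnosis")
    use_mixed = (random_intercept is not None and
                 meta[random_intercept].nunique() > 1)
    if use_mixed:
        groups = meta[random_intercept].to_numpy()
        rows = []
        for g in range(Y.shape[0]):
            fit = fit_random_intercept(Y[g], X, groups, names=names)
            rows.append((fit.coef[j], fit.se[j], fit.pvalues[j]))
        log2fc, se, p = map(np.asarray, zip(*rows))
    else:
        fit = ols_fit(Y, X, names=names)
        log2fc, se, p = fit.coef[:, j], fit.se[:, j], fit.pvalues[:, j]
    out = pd.DataFrame({"log2FC": log2fc, "se": se, "p": p, "q": bh_fdr(p)},
                       index=matrix.index.rename("gene"))
    out.attrs["dataset_id"] = dataset_id
    return out


def transcriptome_overlap(dge_a: pd.DataFrame, dge_b: pd.DataFrame,
                          n_permutations: int = 1000, seed: int = 0,
                          alternative: str = "two-sided",
                          pair=("A", "B")) -> OverlapResult:
    """Spearman overlap of two log2FC vectors with a permutation p-value."""
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    shared = dge_a.index.intersection(dge_b.index)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (< 10)")
    a = dge_a.loc[shared, "log2FC"].to_numpy()
    b = dge_b.loc[shared, "log2FC"].to_numpy()
    rho, p = permutation_spearman(a, b, n_permutations, seed, alternative)
    return OverlapResult(pair=tuple(pair), rho=rho, p=p, n_genes=len(shared),
                         n_permutations=n_permutations, seed=seed)


def severity_slope(dge_ref: pd.DataFrame, dge_target: pd.DataFrame,
                   method: str = "principal_axis",
                   reference: str = "ref", target: str = "target") -> SlopeResult:
    """Slope of target log2FC on reference log2FC.

    Principal-axis (default): sign(cov) * sqrt(var_target / var_ref) after
    centering — symmetric in the sense slope(a,b) * slope(b,a) = 1.
    ``method="ols"`` gives the ordinary least-squares slope instead.
    """
    shared = dge_ref.index.intersection(dge_target.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared genes")
    x = dge_ref.loc[shared, "log2FC"].to_numpy()
    y = dge_target.loc[shared, "log2FC"].to_numpy()
    x = x - x.mean()
    y = y - y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0:
        raise ValueError("reference log2FC has zero variance")
    cov = float(x @ y) / (len(x) - 1)
    if method == "principal_axis":
        slope = float(np.sign(cov) if cov != 0 else 1.0) * float(np.sqrt(vy / vx))
    elif method == "ols":
        slope = cov / vx
    else:
        raise ValueError(f"unknown slope method {method!r}")
    return SlopeResult(reference=reference, target=target, slope=float(slope),
                       method=method, n_genes=len(shared))


def rank_overlap_pairs(overlaps: list, alpha: float = 0.05) -> pd.DataFrame:
    """Overlap pairs ordered by descending rho; ties broken by pair name."""
    if not overlaps:
        raise ValueError("no overlap results supplied")
    rows = [
        {"pair": "~".join(o.pair), "rho": o.rho, "p": o.p,
         "n_genes": o.n_genes, "significant": o.p < alpha}
        for o in overlaps
    ]
    df = pd.DataFrame(rows).sort_values(["rho", "pair"],
                                        ascending=[False, True],
                                        kind="mergesort")
    return df.reset_index(drop=True)
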