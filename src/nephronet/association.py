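"""Module-trait association and hub-gene extraction.

Each module eigengene is regressed on a trait (diagnosis coded control=0,
case=1, so a positive beta means up-regulated in disease) plus optional
covariates; with several studies combined, a random intercept per study
absorbs between-study eigengene offsets. FDR is controlled over all
module x trait tests in one family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_fdr, fit_random_intercept, ols_fit


def _trait_vector(metadata: pd.DataFrame, trait: str) -> np.ndarray:
    x = metadata[trait]
    if trait == "diagnosis" or not pd.api.types.is_numeric_dtype(x):
        levels = sorted(x.unique())
        if len(levels) != 2:
            raise ValueError(f"trait {trait!r} must be binary or numeric")
        # diagnosis: control=0, case=1; otherwise first level alphabetically = 0
        if trait == "diagnosis":
            return (x == "case").astype(float).to_numpy()
        return (x == levels[1]).astype(float).to_numpy()
    return x.astype(float).to_numpy()


def _covariate_design(metadata: pd.DataFrame, covariates) -> list:
    cols = []
    for c in covariates:
        x = metadata[c]
        if pd.api.types.is_numeric_dtype(x):
            cols.append((c, x.astype(float).to_numpy()))
        else:
            d = pd.get_dummies(x, drop_first=True, dtype=float)
            cols.extend((f"{c}[{lvl}]", d[lvl].to_numpy()) for lvl in d.columns)
    return cols


def associate_modules(eigengenes: pd.DataFrame, metadata: pd.DataFrame,
                      traits=("diagnosis",), covariates=(),
                      random_intercept: str | None = None) -> pd.DataFrame:
    """Regress every eigengene on every trait; BH FDR over all tests."""
    if not eigengenes.columns.equals(metadata.index):
        metadata = metadata.loc[eigengenes.columns]
    use_mixed = (random_intercept is not None
                 and metadata[random_intercept].nunique() > 1)
    groups = metadata[random_intercept].to_numpy() if use_mixed else None
    rows = []
    for trait in traits:
        t = _trait_vector(metadata, trait)
        if np.ptp(t) == 0:
            raise ValueError(f"trait {trait!r} is constant")
        cov_cols = _covariate_design(metadata, covariates)
        names = ["intercept", trait] + [n for n, _ in cov_cols]
        X = np.column_stack([np.ones(len(t)), t] + [v for _, v in cov_cols])
        for module in eigengenes.index:
            y = eigengenes.loc[module].to_numpy(dtype=float)
            if use_mixed:
                fit = fit_random_intercept(y, X, groups, names=names)
                beta, se, p = fit.coef[1], fit.se[1], fit.pvalues[1]
            else:
                fit = ols_fit(y, X, names=names)
                beta, se, p = fit.coef[0, 1], fit.se[0, 1], fit.pvalues[0, 1]
            rows.append({"module": module, "trait": trait, "beta": float(beta),
                         "se": float(se), "p": float(p),
                         "direction": "up" if beta > 0 else "down"})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["module", "trait", "beta", "se", "p", "q", "direction"]]


def associate_covariates(eigengenes: pd.DataFrame, metadata: pd.DataFrame,
                         covariates=("rin", "bias_53")) -> pd.DataFrame:
    """Simple per-module linear regressions on continuous covariates.

    Constant covariates are skipped with a note; R^2 reported alongside the
    slope so a perfectly explanatory covariate is obvious.
    """
    if not eigengenes.columns.equals(metadata.index):
        metadata = metadata.loc[eigengenes.columns]
    rows = []
    for cov in covariates:
        x = metadata[cov].astype(float).to_numpy()
        if np.ptp(x) == 0:
            rows.append({"module": None, "covariate": cov, "beta": np.nan,
                         "p": np.nan, "r2": np.nan,
                         "note": "skipped (constant)"})
            continue
        X = np.column_stack([np.ones(len(x)), x])
        for module in eigengenes.index:
            y = eigengenes.loc[module].to_numpy(dtype=float)
            fit = ols_fit(y, X, names=["intercept", cov])
            resid = y - X @ fit.coef[0]
            ss_tot = ((y - y.mean()) ** 2).sum()
            r2 = 1.0 - (resid ** 2).sum() / ss_tot if ss_tot > 0 else np.nan
            rows.append({"module": module, "covariate": cov,
                         "beta": float(fit.coef[0, 1]),
                         "p": float(fit.pvalues[0, 1]), "r2": float(r2),
                         "note": ""})
    out = pd.DataFrame(rows)
    tested = out["note"] == ""
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


def hub_genes(kme_matrix: pd.DataFrame, partition, module: str,
              top_n: int = 20) -> pd.DataFrame:
    """Top module members by own-module kME; ties break by gene ID."""
    members = partition.members(module)
    if len(members) == 0:
        raise ValueError(f"module {module!r} has no members")
    if len(members) < top_n:
        import warnings
        warnings.warn(f"module {module!r} has only {len(members)} members")
    k = kme_matrix.loc[members, module]
    order = sorted(members, key=lambda g: (-k[g], g))
    chosen = order[:top_n]
    return pd.DataFrame({"gene": chosen,
                         "kME": [float(k[g]) for g in chosen],
                         "rank": np.arange(1, len(chosen) + 1)})
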