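"""Expression QC and normalization.

Order of operations mirrors the study design: log2 transform, quantile
normalization, connectivity-based outlier removal, case/control covariate
balance check, empirical-Bayes batch adjustment, probe collapsing by maximum
mean signal, and cross-study gene intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

@dataclass
class QCReport:
    """Auditable log of sample-outlier removal and covariate balance."""

    removed_samples: list = field(default_factory=list)  # (iteration, sample, Z)
    balance: pd.DataFrame | None = None
    iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "removed_samples": [
                {"iteration": it, "sample": s, "z": float(z)}
                for it, s, z in self.removed_samples
            ],
            "iterations": self.iterations,
            "balance": (self.balance.to_dict(orient="records")
                        if self.balance is not None else None),
        }


def log2_transform(matrix: pd.DataFrame, offset: float = 0.0,
                   already_log2: bool = False) -> pd.DataFrame:
    """Entrywise log2(value + offset); identity when flagged already-log2."""
    if already_log2:
        return matrix
    vals = matrix.to_numpy(dtype=float) + offset
    if np.any(vals <= 0):
        i, j = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive value at gene {matrix.index[i]!r}, sample "
            f"{matrix.columns[j]!r} (use a positive offset)")
    return pd.DataFrame(np.log2(vals), index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample to the common distribution of sorted-row means.

    Ties within a column receive the mean of the tied target quantiles.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("missing or non-finite values; impute first")
    target = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(target)
        ranked[order] = target
        # average target values across ties
        s = pd.Series(ranked).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def impute_gene_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries with the gene's mean (explicit opt-in)."""
    vals = matrix.to_numpy(dtype=float)
    means = np.nanmean(vals, axis=1)
    idx = np.where(np.isnan(vals))
    vals = vals.copy()
    vals[idx] = means[idx[0]]
    return pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)


def sample_connectivity_z(matrix: pd.DataFrame) -> pd.Series:
    """Standardized sample-network connectivity Z-scores.

    k_s is the sum of Pearson correlations of sample s with all others
    (computed across genes); Z standardizes k. A constant sample correlates
    0 with everything (warning). If all k are equal, every Z is 0.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant sample(s); their correlations set to 0")
    centered = vals - vals.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    norms[norms == 0] = np.inf
    C = (centered / norms).T @ (centered / norms)
    np.fill_diagonal(C, 0.0)
    k = C.sum(axis=1)
    s = k.std(ddof=1)
    z = np.zeros_like(k) if s == 0 else (k - k.mean()) / s
    return pd.Series(z, index=matrix.columns, name="connectivity_z")


def remove_outliers(matrix: pd.DataFrame, metadata: pd.DataFrame,
                    z_threshold: float = -2.0, max_iterations: int = 10):
    """Iteratively drop samples with connectivity Z below the threshold.

    Recomputes Z after each removal round until none remain (or the
    iteration cap). Refuses to empty either diagnosis group.
    """
    if matrix.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    mat, meta = matrix.copy(), metadata.copy()
    report = QCReport()
    for it in range(1, max_iterations + 1):
        z = sample_connectivity_z(mat)
        bad = z.index[z < z_threshold]
        if len(bad) == 0:
            break
        remaining = meta.drop(index=bad)
        for level in ("case", "control"):
            if (meta["diagnosis"] == level).any() and \
                    not (remaining["diagnosis"] == level).any():
                raise ValueError(
                    f"outlier removal would delete every {level} sample")
        for s in bad:
            report.removed_samples.append((it, s, float(z[s])))
        mat = mat.drop(columns=bad)
        meta = remaining
        report.iterations = it
    return mat, meta, report


def check_balance(metadata: pd.DataFrame, covariates=None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Test each covariate for association with case/control status.

    Categorical covariates: chi-square on the contingency table, switching
    to Fisher's exact for 2x2 tables with any expected cell < 5. Continuous
    covariates: Wilcoxon rank-sum. Constant covariates are skipped.
    """
    diag = metadata["diagnosis"]
    if diag.nunique() < 2:
        raise ValueError("both diagnosis levels required")
    if covariates is None:
        covariates = [c for c in metadata.columns
                      if c not in ("diagnosis", "study")]
    rows = []
    for cov in covariates:
        x = metadata[cov]
        if x.nunique() <= 1:
            rows.append((cov, "skipped (constant)", np.nan, False))
            continue
        if pd.api.types.is_numeric_dtype(x) and x.nunique() > 8:
            a = x[diag == "case"]
            b = x[diag == "control"]
            stat = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append((cov, "wilcoxon_rank_sum", float(stat.pvalue),
                         stat.pvalue <= alpha))
        else:
            table = pd.crosstab(x, diag)
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            test = "chi_square"
            # small expected counts: exact test for 2x2 tables
            if (expected <= 5).any() and table.shape == (2, 2):
                _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
                test = "fisher_exact"
            elif (expected <= 5).any():
                test = "chi_square (small cells)"
            rows.append((cov, test, float(p), p <= alpha))
    return pd.DataFrame(rows, columns=["covariate", "test", "p", "flagged"])


def _batch_design(metadata: pd.DataFrame, batch_col: str, preserve):
    batch = pd.Categorical(metadata[batch_col])
    B = pd.get_dummies(pd.Series(batch, index=metadata.index), dtype=float)
    covs = []
    for c in preserve:
        x = metadata[c]
        if pd.api.types.is_numeric_dtype(x):
            covs.append(x.astype(float).rename(c))
        else:
            d = pd.get_dummies(x, drop_first=True, dtype=float)
            d.columns = [f"{c}[{lvl}]" for lvl in d.columns]
            covs.extend(d[col] for col in d.columns)
    X = pd.concat([B] + covs, axis=1) if covs else B
    full = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            f"batch is confounded with preserved covariates {list(preserve)}")
    return B, X


def adjust_batch_empirical_bayes(matrix: pd.DataFrame, metadata: pd.DataFrame,
                                 batch_col: str = "batch",
                                 preserve=("diagnosis",),
                                 eb_iterations: int = 200,
                                 conv: float = 1e-5) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment (ComBat).

    Per gene: fit batch means plus preserved covariates; standardize against
    pooled variance; shrink per-batch location (normal prior) and scale
    (inverse-gamma prior, method-of-moments hyperparameters, iterative joint
    solution); remove the shrunken batch effects and restore the grand fit.
    """
    batches = pd.unique(metadata[batch_col])
    if len(batches) < 2:
        return matrix
    counts = metadata[batch_col].value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"batch(es) with a single sample: {small}")
    B, X = _batch_design(metadata, batch_col, preserve)
    Y = matrix.to_numpy(dtype=float)  # genes x samples
    n = Y.shape[1]
    Xv = X.to_numpy(dtype=float)
    coef = np.linalg.lstsq(Xv, Y.T, rcond=None)[0].T   # genes x params
    n_batches = B.shape[1]
    batch_sizes = B.to_numpy().sum(axis=0)
    grand_batch = coef[:, :n_batches] @ (batch_sizes / n)   # weighted alpha_g
    # stand_mean: alpha + covariate contribution (batch part replaced by alpha)
    fit_cov = coef[:, n_batches:] @ Xv[:, n_batches:].T if Xv.shape[1] > n_batches \
        else 0.0
    stand_mean = grand_batch[:, None] + fit_cov
    resid = Y - coef @ Xv.T
    var_pooled = np.maximum((resid ** 2).mean(axis=1), 1e-12)
    sd = np.sqrt(var_pooled)[:, None]
    # standardized data retain the batch deviations gamma plus noise
    Zfull = (Y - stand_mean) / sd
    adjusted = Y.astype(float).copy()
    Bv = B.to_numpy(dtype=bool)
    for b in range(n_batches):
        cols = Bv[:, b]
        m = int(cols.sum())
        Zb = Zfull[:, cols]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        d_mean, d_var = delta_hat.mean(), delta_hat.var(ddof=1)
        if d_var > 1e-12:
            lam = (2.0 * d_var + d_mean ** 2) / d_var          # a prior
            theta = (d_mean * d_var + d_mean ** 3) / d_var      # b prior
        else:
            lam = theta = None
        gamma_star = gamma_hat.copy()
        delta_star = np.maximum(delta_hat.copy(), 1e-12)
        for _ in range(eb_iterations):
            if tau2 > 1e-12:
                g_new = (m * tau2 * gamma_hat + delta_star * gamma_bar) / \
                    (m * tau2 + delta_star)
            else:
                g_new = np.full_like(gamma_hat, gamma_bar)
            if lam is not None:
                ss = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (theta + 0.5 * ss) / (m / 2.0 + lam - 1.0)
            else:
                d_new = delta_star
            change = max(np.max(np.abs(g_new - gamma_star)),
                         np.max(np.abs(d_new - delta_star)))
            gamma_star, delta_star = g_new, np.maximum(d_new, 1e-12)
            if change < conv:
                break
        adjusted[:, cols] = sd * (Zb - gamma_star[:, None]) / \
            np.sqrt(delta_star)[:, None] + stand_mean[:, cols]
    return pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: the probe with the largest mean across samples.

    Ties break to the lexicographically smallest probe ID. Rows are copies
    of probe rows, never averages.
    """
    mapping = probe_map.set_index("probe_id")["gene_id"]
    missing = probe_matrix.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"probes absent from the map: {sorted(missing)[:5]}")
    means = probe_matrix.mean(axis=1)
    frame = pd.DataFrame({
        "gene": mapping.reindex(probe_matrix.index).to_numpy(),
        "mean": means.to_numpy(),
        "probe": probe_matrix.index.to_numpy(),
    })
    frame = frame.sort_values(["gene", "mean", "probe"],
                              ascending=[True, False, True], kind="mergesort")
    best = frame.groupby("gene", sort=True).first()["probe"]
    out = probe_matrix.loc[best.to_numpy()].copy()
    out.index = pd.Index(best.index, name="gene")
    return out


def intersect_genes(matrices: list):
    """Sorted gene-ID intersection plus each matrix restricted to it."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index)
    common = sorted(common)
    if not common:
        raise ValueError("empty gene intersection")
    return common, [m.loc[common] for m in matrices]
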