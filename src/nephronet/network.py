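"""Signed weighted gene co-expression network, built from first principles.

The pipeline: biweight midcorrelation between gene profiles, signed
soft-threshold adjacency a_ij = ((1 + c_ij)/2)^beta, topological overlap,
average-linkage clustering of 1 - TOM, a hybrid dynamic-style tree cut with
a size filter (PAM reassignment off), module eigengenes (first principal
component), module membership kME, eigengene-based module merging, and
resampling-based robustness scoring.

The tree cut is a deliberately simplified static-threshold variant of the
dynamic hybrid method: the cut height is a deep-split-dependent quantile of
the merge-height distribution, and branches below it with at least
``min_module_size`` leaves become modules. Planted-module recovery, not
equality with any particular reference implementation, is the design target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .simulate import GREY, MODULE_COLORS

#: deep_split -> fraction of the (median, max) merge-height range used as cut
DEEP_SPLIT_QUANTILE = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


@dataclass
class NetworkParams:
    """All tunables of the network stage (defaults follow the study design)."""

    network_sign: str = "signed"
    beta: int = 9
    min_module_size: int = 100
    deep_split: int = 3
    merge_cut_height: float = 0.1
    pam_stage: bool = False
    n_resamples: int = 100
    resample_fraction: float = 2.0 / 3.0
    seed: int = 0
    r2_target: float = 0.8
    kme_method: str = "pearson"   # or "bicor"

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if not 0.0 < self.resample_fraction <= 1.0:
            raise ValueError("resample_fraction must be in (0, 1]")
        if self.deep_split not in DEEP_SPLIT_QUANTILE:
            raise ValueError("deep_split must be in 0..4")
        if self.pam_stage:
            raise NotImplementedError("PAM reassignment stage is disabled")


@dataclass
class ModulePartition:
    """Gene -> module label assignment; ``grey`` marks unassigned genes."""

    labels: pd.Series                      # gene -> color label
    stability: pd.Series | None = None     # gene -> resampling stability

    @property
    def modules(self) -> list[str]:
        """Non-grey module labels, largest first (ties by name)."""
        counts = self.labels[self.labels != GREY].value_counts()
        return sorted(counts.index, key=lambda m: (-counts[m], m))

    def members(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def grey_fraction(self) -> float:
        return float((self.labels == GREY).mean())


def _bicor_prepare(X: np.ndarray) -> np.ndarray:
    """Row-wise biweight transform: centered, Tukey-biweighted, unit norm.

    Rows with zero MAD fall back to Pearson standardization (with a warning);
    constant rows become all-zero, so their correlation with anything is 0.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = (mad[:, 0] == 0)
    out = np.empty_like(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        out[:] = dev * w
    if np.any(zero_mad):
        warnings.warn(f"{int(zero_mad.sum())} vector(s) with zero MAD; "
                      "falling back to Pearson for them")
        mean_dev = X[zero_mad] - X[zero_mad].mean(axis=1, keepdims=True)
        out[zero_mad] = mean_dev
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    out[nz] /= norms[nz]
    out[~nz] = 0.0
    return out


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (robust to outliers)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    t = _bicor_prepare(np.vstack([x, y]))
    return float(np.clip(t[0] @ t[1], -1.0, 1.0))


def bicor_matrix(X) -> np.ndarray:
    """All-pairs biweight midcorrelation of the rows of ``X``."""
    t = _bicor_prepare(np.asarray(X, dtype=float))
    C = t @ t.T
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


def signed_adjacency(C: np.ndarray, beta: int = 9) -> np.ndarray:
    """Signed adjacency ((1 + c)/2)^beta with a zero diagonal."""
    C = np.asarray(C, dtype=float)
    if np.any(np.abs(C) > 1.0 + 1e-8):
        raise ValueError("correlations must lie in [-1, 1]")
    A = ((1.0 + np.clip(C, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def scale_free_fit(A: np.ndarray, n_bins: int = 10):
    """Signed R^2 of the log-log connectivity-distribution fit, and mean k.

    Connectivities are split into equal-count bins; the regression is of
    log10 density (bin count / (n * bin width)) on log10 mean connectivity.
    The R^2 is multiplied by -sign(slope), so decaying distributions score
    positive. Degenerate (all-equal k) input scores 0.
    """
    k = np.asarray(A, dtype=float).sum(axis=0)
    mean_k = float(k.mean())
    if np.ptp(k) < 1e-12:
        return 0.0, mean_k
    order = np.argsort(k)
    chunks = np.array_split(k[order], n_bins)
    xs, ys = [], []
    n = k.size
    for c in chunks:
        if c.size == 0:
            continue
        width = c.max() - c.min()
        if width <= 0 or c.mean() <= 0:
            continue
        xs.append(np.log10(c.mean()))
        ys.append(np.log10(c.size / (n * width)))
    if len(xs) < 3:
        return 0.0, mean_k
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = np.polyval([slope, intercept], xs)
    ss_res = np.sum((np.asarray(ys) - fitted) ** 2)
    ss_tot = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), mean_k


def pick_soft_threshold(X, beta_grid=range(1, 21), r2_target: float = 0.8,
                        default_beta: int = 9):
    """Smallest beta reaching the scale-free R^2 target, else the default."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 50:
        raise ValueError("need at least 50 genes to assess scale-free fit")
    C = bicor_matrix(X)
    for beta in beta_grid:
        r2, _ = scale_free_fit(signed_adjacency(C, beta))
        if r2 >= r2_target:
            return int(beta)
    warnings.warn(f"no beta in the grid reached R^2 >= {r2_target}; "
                  f"using default {default_beta}")
    return int(default_beta)


def tom(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any((A < -1e-12) | (A > 1.0 + 1e-12)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.any(np.abs(np.diag(A)) > 1e-12):
        raise ValueError("adjacency diagonal must be zero")
    k = A.sum(axis=0)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    T = num / den
    np.fill_diagonal(T, 1.0)
    return T


def tom_dissimilarity(A: np.ndarray) -> np.ndarray:
    return 1.0 - tom(A)


def hclust_average(D: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) tree of a dissimilarity matrix.

    Returns the scipy linkage matrix (merge list with heights).
    """
    D = np.asarray(D, dtype=float)
    if np.any(~np.isfinite(D)):
        raise ValueError("dissimilarity contains non-finite values")
    if not np.allclose(D, D.T, atol=1e-10) or np.any(np.abs(np.diag(D)) > 1e-10):
        raise ValueError("need a symmetric dissimilarity with zero diagonal")
    return linkage(squareform(D, checks=False), method="average")


def _module_counts_by_merge(Z: np.ndarray, min_module_size: int) -> np.ndarray:
    """After each merge, how many current clusters have >= min size.

    Incremental union-find over the merge list; counts[i] is the number of
    qualifying clusters once all merges up to and including i are applied.
    """
    n = Z.shape[0] + 1
    parent = np.arange(2 * n - 1)
    size = np.concatenate([np.ones(n, dtype=int), np.zeros(n - 1, dtype=int)])

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    counts = np.empty(n - 1, dtype=int)
    c = n if min_module_size <= 1 else 0
    for i in range(n - 1):
        ra, rb = find(int(Z[i, 0])), find(int(Z[i, 1]))
        sa, sb = size[ra], size[rb]
        new = n + i
        parent[ra] = parent[rb] = new
        size[new] = sa + sb
        c += int(sa + sb >= min_module_size) - int(sa >= min_module_size) \
            - int(sb >= min_module_size)
        counts[i] = c
    return counts


def cut_dynamic_hybrid(Z: np.ndarray, gene_ids, min_module_size: int = 100,
                       deep_split: int = 3, pam_stage: bool = False) -> ModulePartition:
    """Static-height variant of the hybrid dynamic tree cut (PAM off).

    ``deep_split`` bounds the search region (its quantile of the merge-height
    range, higher = wider). Within that region the rule scans every possible
    cut, keeps the heights whose cut yields the maximum number of branches
    with at least ``min_module_size`` leaves, and places the cut inside the
    widest merge-height gap of that plateau — the valley separating
    within-module merges from background attachments. Branches at the cut
    with >= min size become modules; all remaining leaves are grey. Module
    count is therefore non-decreasing in ``deep_split``. Modules are named
    by the color palette, largest first.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if pam_stage:
        raise NotImplementedError("PAM reassignment stage is disabled")
    heights = Z[:, 2]
    n = Z.shape[0] + 1
    h_min, h_max = float(heights.min()), float(heights.max())
    q = DEEP_SPLIT_QUANTILE[deep_split]
    bound = h_min + q * (h_max - h_min)
    counts = _module_counts_by_merge(Z, min_module_size)
    labels = pd.Series(GREY, index=pd.Index(gene_ids, name="gene"), name="module")
    valid = heights <= bound + 1e-15
    if not valid.any() or counts[valid].max() == 0:
        return ModulePartition(labels=labels)
    max_count = counts[valid].max()
    plateau = np.flatnonzero(valid & (counts == max_count))
    gaps = np.empty(n - 1)
    gaps[:-1] = heights[1:] - heights[:-1]
    gaps[-1] = 0.0
    best = plateau[int(np.argmax(gaps[plateau]))]
    h_cut = heights[best] + gaps[best] / 2.0 if best < n - 2 else heights[best]
    flat = fcluster(Z, t=h_cut, criterion="distance")
    sizes = pd.Series(flat).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    # largest first; ties by first gene position for determinism
    keep.sort(key=lambda c: (-sizes[c], int(np.argmax(flat == c))))
    for color, cluster in zip(MODULE_COLORS, keep):
        labels.iloc[np.flatnonzero(flat == cluster)] = color
    for i, cluster in enumerate(keep[len(MODULE_COLORS):]):
        labels.iloc[np.flatnonzero(flat == cluster)] = f"module{len(MODULE_COLORS) + i}"
    return ModulePartition(labels=labels)


def module_eigengene(X: pd.DataFrame, member_genes) -> pd.Series:
    """First principal component of the z-scored member submatrix.

    Scaled to unit variance, sign-oriented so the mean correlation with
    member genes is positive. Constant genes are dropped with a warning.
    """
    sub = X.loc[list(member_genes)].to_numpy(dtype=float)
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 member genes")
    sd = sub.std(axis=1, ddof=1)
    const = sd == 0
    if const.all():
        raise ValueError("all member genes are constant")
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant gene(s) from eigengene")
        sub, sd = sub[~const], sd[~const]
    zs = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # first right singular vector = PC scores over samples
    _, _, vt = np.linalg.svd(zs, full_matrices=False)
    me = vt[0]
    me = (me - me.mean()) / me.std(ddof=1)
    r = zs @ me / ((zs.shape[1] - 1) * zs.std(axis=1, ddof=1) * me.std(ddof=1))
    if r.mean() < 0:
        me = -me
    return pd.Series(me, index=X.columns, name="eigengene")


def eigengene_matrix(X: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """Module x sample eigengene matrix for all non-grey modules."""
    rows = {m: module_eigengene(X, partition.members(m))
            for m in partition.modules}
    if not rows:
        return pd.DataFrame(columns=X.columns)
    return pd.DataFrame(rows).T.set_axis(X.columns, axis=1)


def kme(X: pd.DataFrame, eigengenes: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Module membership: correlation of every gene with every eigengene."""
    if not X.columns.equals(eigengenes.columns):
        raise ValueError("expression and eigengenes cover different samples")
    if eigengenes.shape[0] == 0:
        return pd.DataFrame(index=X.index)
    if method == "pearson":
        Xv = X.to_numpy(dtype=float)
        Ev = eigengenes.to_numpy(dtype=float)
        Xc = Xv - Xv.mean(axis=1, keepdims=True)
        Ec = Ev - Ev.mean(axis=1, keepdims=True)
        xn = np.linalg.norm(Xc, axis=1)
        en = np.linalg.norm(Ec, axis=1)
        xn[xn == 0] = np.inf
        K = (Xc @ Ec.T) / np.outer(xn, en)
    elif method == "bicor":
        tx = _bicor_prepare(X.to_numpy(dtype=float))
        te = _bicor_prepare(eigengenes.to_numpy(dtype=float))
        K = tx @ te.T
    else:
        raise ValueError(f"unknown kME method {method!r}")
    return pd.DataFrame(np.clip(K, -1.0, 1.0), index=X.index,
                        columns=eigengenes.index)


def merge_close_modules(X: pd.DataFrame, partition: ModulePartition,
                        merge_cut_height: float = 0.1):
    """Merge modules whose eigengenes are closer than the cut height.

    Iterates: find the closest eigengene pair; if 1 - cor < cut, merge the
    smaller into the larger and recompute, until no pair qualifies. Returns
    the (relabelled, size-ordered) partition and its eigengenes.
    """
    labels = partition.labels.copy()
    while True:
        part = ModulePartition(labels=labels)
        mods = part.modules
        ME = eigengene_matrix(X, part)
        if len(mods) < 2 or merge_cut_height <= 0:
            break
        C = np.corrcoef(ME.loc[mods].to_numpy())
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] >= merge_cut_height:
            break
        big, small = mods[min(i, j)], mods[max(i, j)]
        labels[labels == small] = big
    # relabel by size for deterministic naming
    final = ModulePartition(labels=labels)
    mapping = {old: MODULE_COLORS[k] if k < len(MODULE_COLORS) else f"module{k}"
               for k, old in enumerate(final.modules)}
    mapping[GREY] = GREY
    labels = labels.map(mapping)
    final = ModulePartition(labels=labels)
    return final, eigengene_matrix(X, final)


def detect_modules(X: pd.DataFrame, params: NetworkParams) -> ModulePartition:
    """Full detection pass: bicor -> adjacency -> TOM -> UPGMA -> cut -> merge."""
    C = bicor_matrix(X.to_numpy(dtype=float))
    A = signed_adjacency(C, params.beta)
    D = tom_dissimilarity(A)
    Z = hclust_average(D)
    part = cut_dynamic_hybrid(Z, X.index, params.min_module_size,
                              params.deep_split, params.pam_stage)
    if len(part.modules) >= 2:
        part, _ = merge_close_modules(X, part, params.merge_cut_height)
    return part


def robustness_consensus(X: pd.DataFrame, params: NetworkParams,
                         full_partition: ModulePartition | None = None):
    """Resampling stability of module assignments.

    Detection is repeated on ``n_resamples`` sample subsets (fraction
    ``resample_fraction``, without replacement). A gene is stable in a
    resample when it lands in the same resample-module as the majority of
    its full-data module; genes with stability < 0.5 are re-assigned grey.
    """
    n = X.shape[1]
    if n < 12:
        raise ValueError("need at least 12 samples for resampling")
    size = int(np.ceil(params.resample_fraction * n))
    if size < 5:
        raise ValueError("resample would contain fewer than 5 samples")
    if full_partition is None:
        full_partition = detect_modules(X, params)
    labels = full_partition.labels
    rng = np.random.default_rng(params.seed)
    stable_counts = pd.Series(0.0, index=labels.index)
    groups = {m: labels.index[labels == m] for m in labels.unique()}
    for _ in range(params.n_resamples):
        cols = np.sort(rng.choice(n, size=size, replace=False))
        sub = X.iloc[:, cols]
        part_r = detect_modules(sub, params)
        rl = part_r.labels
        for m, members in groups.items():
            member_labels = rl.loc[members]
            majority = member_labels.mode().sort_values().iloc[0]
            stable_counts.loc[members] += (member_labels == majority).astype(float)
    stability = stable_counts / params.n_resamples
    final = labels.copy()
    final[(stability < 0.5) & (labels != GREY)] = GREY
    return stability.rename("stability"), ModulePartition(labels=final,
                                                          stability=stability)


def adjusted_rand_index(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Adjusted Rand index between two labelings over their shared genes."""
    from sklearn.metrics import adjusted_rand_score
    common = labels_a.index.intersection(labels_b.index)
    return float(adjusted_rand_score(labels_a.loc[common], labels_b.loc[common]))
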