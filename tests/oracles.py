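"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (loops, explicit sums) and shares no
code with the package.
"""

import math

import numpy as np


def bicor_oracle(x, y):
    """Direct scalar evaluation of the biweight midcorrelation formula."""
    def weights(v):
        v = np.asarray(v, dtype=float)
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        if mad == 0:
            return None, med
        u = (v - med) / (9.0 * mad)
        w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
        return w, med

    wx, medx = weights(x)
    wy, medy = weights(y)
    if wx is None or wy is None:
        # Pearson fallback
        return float(np.corrcoef(x, y)[0, 1])
    a = (np.asarray(x) - medx) * wx
    b = (np.asarray(y) - medy) * wy
    return float(np.sum(a * b) / (np.sqrt(np.sum(a ** 2)) * np.sqrt(np.sum(b ** 2))))


def tom_oracle(A):
    """Triple-loop topological overlap."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    k = A.sum(axis=0)
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                T[i, j] = 1.0
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n))
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return T


def upgma_cophenetic_oracle(D):
    """Naive UPGMA; returns the cophenetic distance matrix."""
    D = np.asarray(D, dtype=float).copy()
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        new_dist = {}
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        for c, members in clusters.items():
            d = np.mean([D[i, j] for i in merged for j in members])
            new_dist[(min(c, next_id), max(c, next_id))] = d
        clusters[next_id] = merged
        dist.update(new_dist)
        next_id += 1
    return coph


def bh_oracle(p):
    """Literal Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def fisher_greater_oracle(a, b, c, d):
    """One-sided (enrichment) Fisher p by explicit hypergeometric summation."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def hyper(k):
        return (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                / math.comb(n, row1))

    return sum(hyper(k) for k in range(a, min(row1, col1) + 1))


def sidak_oracle(min_p, n):
    return 1.0 - (1.0 - min_p) ** n
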