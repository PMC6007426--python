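"""Independent scalar oracles used by the test suite.

These are deliberately naive transliterations (explicit loops, textbook
formulas) kept separate from the vectorized implementation paths they
check.
"""

import itertools
import math

import numpy as np


def pi_brute_force(n, j):
    """Mean pairwise difference over all C(n,2) haplotype pairs."""
    haps = [1] * j + [0] * (n - j)
    pairs = list(itertools.combinations(range(n), 2))
    return sum(haps[a] != haps[b] for a, b in pairs) / len(pairs)


def wc_site_oracle(genotypes_by_pop):
    """Weir & Cockerham (1984) a, b, c for one biallelic site.

    ``genotypes_by_pop``: list (one entry per population) of lists of
    diploid genotype codes 0/1/2 (missing excluded by the caller).
    Returns (a, b, c) or None when undefined.
    """
    r = len(genotypes_by_pop)
    ns = [len(g) for g in genotypes_by_pop]
    if sum(n >= 1 for n in ns) < 2:
        return None
    ps = [sum(g) / (2.0 * n) for g, n in zip(genotypes_by_pop, ns)]
    hs = [sum(1 for x in g if x == 1) / n for g, n in zip(genotypes_by_pop, ns)]
    nbar = sum(ns) / r
    if nbar <= 1:
        return None
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def windowed_fst_oracle(gt, idx_a, idx_b):
    """Ratio-of-sums theta-hat over all sites of a genotype matrix."""
    num = den = 0.0
    for row in gt:
        pops = []
        for idx in (idx_a, idx_b):
            pops.append([int(row[i]) for i in idx if row[i] >= 0])
        if any(len(g) == 0 for g in pops):
            continue
        comps = wc_site_oracle(pops)
        if comps is None:
            continue
        a, b, c = comps
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def window_pi_oracle(gt, idx, length):
    """Summed per-site mean pairwise differences / window length."""
    total = 0.0
    for row in gt:
        calls = [int(row[i]) for i in idx if row[i] >= 0]
        n = 2 * len(calls)
        if n < 2:
            continue
        j = sum(calls)
        total += pi_brute_force(n, j) if 0 < j < n else 0.0
    return total / length


def cluster_filter_oracle(positions, window_bp=10, max_snps=3):
    """O(n^2) check: SNP dropped iff some window_bp interval containing it
    holds more than max_snps SNPs."""
    positions = list(positions)
    drop = []
    for p in positions:
        bad = False
        for start in range(p - window_bp + 1, p + 1):
            count = sum(1 for q in positions if start <= q <= start + window_bp - 1)
            if count > max_snps:
                bad = True
                break
        drop.append(bad)
    return drop


def projection_oracle(j, n, m):
    """Exhaustive enumeration of all C(n,m) subsamples."""
    haps = [1] * j + [0] * (n - j)
    counts = np.zeros(m + 1)
    subsets = list(itertools.combinations(range(n), m))
    for sub in subsets:
        counts[sum(haps[i] for i in sub)] += 1
    return counts / len(subsets)


def interval_overlap_oracle(regions, genes):
    """Brute-force half-open interval intersection: list of gene ids per region."""
    out = []
    for scaf_r, s_r, e_r in regions:
        hits = [gid for scaf_g, s_g, e_g, gid in genes
                if scaf_g == scaf_r and s_g < e_r and s_r < e_g]
        out.append(hits)
    return out


def additive_matrix_from_tree(t_ab, t_a, t_b, t_c, t_d):
    """4-taxon tree ((A,B),(C,D)) with internal edge t_ab: distance matrix."""
    d = np.zeros((4, 4))
    lens = {"A": t_a, "B": t_b, "C": t_c, "D": t_d}
    taxa = ["A", "B", "C", "D"]
    for i, x in enumerate(taxa):
        for jj, y in enumerate(taxa):
            if i == jj:
                continue
            extra = t_ab if {x, y} not in ({"A", "B"}, {"C", "D"}) else 0.0
            d[i, jj] = lens[x] + lens[y] + extra
    return taxa, d


def grm_oracle(gt):
    """Double-loop GRM on mean-imputed dosages."""
    x = np.asarray(gt, dtype=float).T  # samples x sites
    x[x < 0] = np.nan
    p = np.nanmean(x, axis=0) / 2
    keep = (p > 0) & (p < 1)
    x, p = x[:, keep], p[keep]
    n, m = x.shape
    g = np.zeros((n, n))
    for jj in range(n):
        for kk in range(n):
            acc = 0.0
            for s in range(m):
                xj = x[jj, s] if math.isfinite(x[jj, s]) else 2 * p[s]
                xk = x[kk, s] if math.isfinite(x[kk, s]) else 2 * p[s]
                acc += (xj - 2 * p[s]) * (xk - 2 * p[s]) / (2 * p[s] * (1 - p[s]))
            g[jj, kk] = acc / m
    return g


def allele_sharing_oracle(gt):
    x = np.asarray(gt, dtype=float)
    n = x.shape[1]
    d = np.zeros((n, n))
    for jj in range(n):
        for kk in range(n):
            if jj == kk:
                continue
            num = cnt = 0.0
            for row in x:
                if row[jj] >= 0 and row[kk] >= 0:
                    num += abs(row[jj] - row[kk]) / 2
                    cnt += 1
            d[jj, kk] = num / cnt if cnt else 0.0
    return d
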