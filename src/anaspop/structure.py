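"""Population-structure utilities: GRM, PCA, allele-sharing distance, NJ tree.

The genetic relationship matrix follows the standard standardized
genotype cross-product (VanRaden-style, per-site variance weights) on
mean-imputed genotypes; PCA is an eigendecomposition of that matrix.
Allele-sharing distance uses pairwise-complete sites. The
neighbor-joining tree is the canonical Q-matrix agglomeration with
deterministic tie-breaking by taxon order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .variant_io import VariantTable

logger = logging.getLogger("anaspop")


def _dosage_matrix(table: VariantTable):
    """(n_samples, n_sites) float dosages with nan for missing."""
    x = table.gt.T.astype(float)
    x[x < 0] = np.nan
    return x


def grm(table: VariantTable) -> np.ndarray:
    """Genetic relationship matrix on structure-filtered SNPs.

    G_jk = (1/M) sum_m (x_jm - 2 p_m)(x_km - 2 p_m) / (2 p_m (1 - p_m))
    with dosages x in {0,1,2}, allele frequencies p from the sample, and
    missing genotypes mean-imputed per site. Monomorphic sites are
    excluded.
    """
    x = _dosage_matrix(table)
    p = np.nanmean(x, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("grm: excluded %d monomorphic/uncallable sites", n_dropped)
    x = x[:, poly]
    p = p[poly]
    x = np.where(np.isnan(x), 2.0 * p, x)
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = z.shape[1]
    if m == 0:
        raise ValueError("no polymorphic sites for GRM")
    return z @ z.T / m


def pca(matrix: np.ndarray, k: int = 20):
    """Top-k eigenpairs of a symmetric (relationship) matrix.

    Returns (eigenvectors (n, k), eigenvalues (k,), variance-explained
    fractions over the non-negative spectrum), descending.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    w, v = np.linalg.eigh(matrix)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    k = min(k, w.size)
    total = w[w > 0].sum()
    fractions = np.where(w[:k] > 0, w[:k] / total, 0.0) if total > 0 else np.zeros(k)
    # deterministic sign: largest-magnitude entry positive
    for i in range(k):
        j = np.argmax(np.abs(v[:, i]))
        if v[j, i] < 0:
            v[:, i] = -v[:, i]
    return v[:, :k], w[:k], fractions


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{lab:<10s} {row}\n")


def allele_sharing_distance(table: VariantTable) -> DistanceMatrix:
    """Pairwise allele-sharing distance d(j,k) = mean |x_j - x_k| / 2
    over sites called in both samples."""
    x = _dosage_matrix(table)
    n = x.shape[0]
    d = np.zeros((n, n))
    called = ~np.isnan(x)
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:]) / 2.0
        both = called[i] & called[i + 1:]
        with np.errstate(invalid="ignore"):
            vals = np.where(both, diff, 0.0).sum(axis=1) / both.sum(axis=1)
        d[i, i + 1:] = np.where(np.isnan(vals), 0.0, vals)
    d = d + d.T
    return DistanceMatrix(list(table.samples), d)


def population_mean_distance(dm: DistanceMatrix, popmap) -> DistanceMatrix:
    """Collapse a sample distance matrix to population means."""
    pops = popmap.populations
    label_idx = {s: i for i, s in enumerate(dm.labels)}
    out = np.zeros((len(pops), len(pops)))
    for a, pa in enumerate(pops):
        ia = [label_idx[s] for s in popmap.samples_in_pop(pa) if s in label_idx]
        for b in range(a + 1, len(pops)):
            ib = [label_idx[s] for s in popmap.samples_in_pop(pops[b]) if s in label_idx]
            out[a, b] = out[b, a] = float(dm.values[np.ix_(ia, ib)].mean())
    return DistanceMatrix(pops, out)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> str:
    """Canonical neighbor-joining tree (newick, unrooted trifurcation).

    Q(i,j) = (n-2) d(i,j) - R_i - R_j; the minimal pair joins with limb
    lengths d(i,j)/2 +- (R_i - R_j)/(2(n-2)); ties break on the first
    (i, j) pair in taxon order. Two taxa degenerate to a single edge of
    their distance (split across the two limbs). Requires finite
    distances.
    """
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances")
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        d = dm.values[0, 1]
        return f"({labels[0]}:{d / 2:.10g},{labels[1]}:{d / 2:.10g});"

    d = dm.values.astype(float).copy()
    nodes = [str(lab) for lab in labels]  # newick fragments
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best, bi, bj = np.inf, -1, -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best - 1e-15:
                    best, bi, bj = q, i, j
        li = d[bi, bj] / 2.0 + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = d[bi, bj] - li
        new = f"({nodes[bi]}:{li:.10g},{nodes[bj]}:{lj:.10g})"
        dnew = 0.5 * (d[bi] + d[bj] - d[bi, bj])
        keep = [x for x in range(m) if x not in (bi, bj)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:m - 2, :m - 2] = d[np.ix_(keep, keep)]
        d2[m - 2, :m - 2] = d2[:m - 2, m - 2] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [new]
    if len(nodes) == 3:
        l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        return (f"({nodes[0]}:{l0:.10g},{nodes[1]}:{l1:.10g},"
                f"{nodes[2]}:{l2:.10g});")
    # exactly two composite nodes remain (n was even... n==2 handled above)
    return f"({nodes[0]}:{d[0, 1] / 2:.10g},{nodes[1]}:{d[0, 1] / 2:.10g});"
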