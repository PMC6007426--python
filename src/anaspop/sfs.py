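"""Folded joint site-frequency spectra.

Builds 1-3 population folded SFS from a genotype table with
hypergeometric projection to accommodate missing data, selects the
projection sizes that maximize the number of segregating SNPs, thins
sites to reduce linkage, and serializes spectra as plain text.

Folding is on the global minor allele across the pooled populations;
cells at exactly 50% frequency receive half-mass in each mirrored cell.
Non-polymorphic corner cells are masked and carry no mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .variant_io import VariantTable
from .diversity import _counts_matrix

logger = logging.getLogger("anaspop")


@dataclass
class FoldedSFS:
    """Folded (joint) SFS: mass over minor-allele-count bins plus a mask.

    ``mass`` has shape ``(m1+1, ..., mk+1)`` for projected haplotype
    counts ``m_i``; masked cells (True in ``mask``) are the fixed
    corners and the majority half removed by folding.
    """

    mass: np.ndarray
    mask: np.ndarray
    pop_names: tuple = ()

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mass.shape != self.mask.shape:
            raise ValueError("mass and mask shapes differ")

    @property
    def dims(self) -> tuple:
        return tuple(d - 1 for d in self.mass.shape)

    @property
    def n_snps(self) -> float:
        """Total unmasked (segregating) mass."""
        return float(self.mass[~self.mask].sum())

    def normalized(self) -> "FoldedSFS":
        total = self.n_snps
        if total <= 0:
            raise ValueError("empty spectrum")
        mass = np.where(self.mask, 0.0, self.mass / total)
        return FoldedSFS(mass, self.mask.copy(), self.pop_names)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# anaspop folded SFS\n")
            fh.write("dims\t" + "\t".join(str(d) for d in self.mass.shape) + "\n")
            fh.write("pops\t" + "\t".join(self.pop_names) + "\n")
            fh.write("mass\t" + " ".join(repr(float(x)) for x in self.mass.ravel()) + "\n")
            fh.write("mask\t" + " ".join("1" if m else "0" for m in self.mask.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "FoldedSFS":
        fields = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                key, _, rest = line.rstrip("\n").partition("\t")
                fields[key] = rest
        shape = tuple(int(x) for x in fields["dims"].split("\t"))
        pops = tuple(p for p in fields.get("pops", "").split("\t") if p)
        mass = np.array([float(x) for x in fields["mass"].split()]).reshape(shape)
        mask = np.array([x == "1" for x in fields["mask"].split()]).reshape(shape)
        return cls(mass, mask, pops)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_site(j: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric projection of an allele count j out of n haplotypes
    down to m haplotypes: weight(i) = C(j,i) C(n-j, m-i) / C(n,m).

    Weights sum to one; m == n returns the indicator at i = j.
    """
    if not (0 <= j <= n):
        raise ValueError("need 0 <= j <= n")
    if not (1 <= m <= n):
        raise ValueError("need 1 <= m <= n")
    return projection_matrix(n, m)[j]


def projection_matrix(n: int, m: int) -> np.ndarray:
    """All projection rows at once: shape (n+1, m+1), row j = project_site(j, n, m)."""
    if m > n:
        raise ValueError("projection size exceeds sample size")
    j = np.arange(n + 1)[:, None].astype(float)
    i = np.arange(m + 1)[None, :].astype(float)

    def logc(a, b):
        with np.errstate(invalid="ignore"):
            out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return out

    logw = logc(j, i) + logc(n - j, m - i) - logc(float(n), float(m))
    valid = (i <= j) & (m - i <= n - j)
    w = np.where(valid, np.exp(logw), 0.0)
    # guard tiny negative / rounding drift
    w = np.clip(w, 0.0, None)
    w /= w.sum(axis=1, keepdims=True)
    return w


def fold_joint(unfolded: np.ndarray, pop_names=()) -> FoldedSFS:
    """Fold an unfolded joint spectrum on the pooled minor allele.

    Cell (i1..ik) is added to its complement (m1-i1, ..., mk-ik) when the
    pooled count exceeds half the pooled haplotypes; cells at exactly
    half keep half-mass on each side. Masks the zero corner and the
    folded-away majority half.
    """
    unfolded = np.asarray(unfolded, dtype=float)
    dims = tuple(d - 1 for d in unfolded.shape)
    ntot = sum(dims)
    grids = np.indices(unfolded.shape)
    itot = sum(grids)
    reversed_all = unfolded[tuple(slice(None, None, -1) for _ in dims)]
    folded = np.where(2 * itot < ntot, unfolded + reversed_all,
                      np.where(2 * itot == ntot, (unfolded + reversed_all) / 2.0, 0.0))
    mask = (itot == 0) | (2 * itot > ntot)
    folded = np.where(mask, 0.0, folded)
    return FoldedSFS(folded, mask, tuple(pop_names))


def _per_pop_site_counts(table: VariantTable, pops: dict):
    """{pop: (n_hap, alt)} arrays over SNP sites; returns (snp_row_idx, counts)."""
    is_snp = (table.sites["var_class"] == "SNP").to_numpy()
    idx = np.flatnonzero(is_snp)
    sub = table.subset_sites(idx)
    counts = {}
    for name, sample_idx in pops.items():
        n, alt, _ = _counts_matrix(sub, sample_idx)
        counts[name] = (n, alt)
    return idx, counts


def joint_folded_sfs(table: VariantTable, pops: dict, projections: dict):
    """Build the folded joint SFS over the populations in ``pops``.

    Parameters
    ----------
    pops : dict
        population name -> sample index array (defines axis order).
    projections : dict
        population name -> projected haplotype count m.

    Sites where any population has fewer called haplotypes than its
    projection are skipped (and counted). Each retained site contributes
    the outer product of its per-population projection vectors.

    Returns
    -------
    (FoldedSFS, int)
        The folded spectrum and the number of skipped sites.
    """
    names = list(pops)
    ms = [int(projections[p]) for p in names]
    _, counts = _per_pop_site_counts(table, pops)
    ns = [counts[p][0] for p in names]
    js = [counts[p][1] for p in names]
    n_sites = len(ns[0]) if names else 0

    usable = np.ones(n_sites, dtype=bool)
    for n_arr, m in zip(ns, ms):
        usable &= n_arr >= m
    skipped = int(n_sites - usable.sum())
    if skipped:
        logger.info("joint_folded_sfs: skipped %d sites below projection", skipped)

    proj_cache = {}
    unfolded = np.zeros(tuple(m + 1 for m in ms))
    for s in np.flatnonzero(usable):
        vecs = []
        for k, m in enumerate(ms):
            key = (int(ns[k][s]), m)
            if key not in proj_cache:
                proj_cache[key] = projection_matrix(*key)
            vecs.append(proj_cache[key][int(js[k][s])])
        contrib = vecs[0]
        for v in vecs[1:]:
            contrib = np.multiply.outer(contrib, v)
        unfolded += contrib
    return fold_joint(unfolded, names), skipped


def segregating_mass(table: VariantTable, pops: dict, projections: dict) -> float:
    """Expected segregating-SNP mass for given projection sizes.

    Computed in closed form from the per-site probabilities that the
    projected pooled sample is monomorphic:
    1 - prod_p P(i_p = 0) - prod_p P(i_p = m_p).
    """
    names = list(pops)
    ms = [int(projections[p]) for p in names]
    _, counts = _per_pop_site_counts(table, pops)
    ns = [counts[p][0].astype(float) for p in names]
    js = [counts[p][1].astype(float) for p in names]
    n_sites = len(ns[0]) if names else 0
    usable = np.ones(n_sites, dtype=bool)
    for n_arr, m in zip(ns, ms):
        usable &= n_arr >= m

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    p_all0 = np.ones(n_sites)
    p_allm = np.ones(n_sites)
    for n_arr, j_arr, m in zip(ns, js, ms):
        with np.errstate(invalid="ignore"):
            p0 = np.where(n_arr - j_arr >= m, np.exp(logc(n_arr - j_arr, m) - logc(n_arr, m)), 0.0)
            pm = np.where(j_arr >= m, np.exp(logc(j_arr, m) - logc(n_arr, m)), 0.0)
        p_all0 *= p0
        p_allm *= pm
    seg = 1.0 - p_all0 - p_allm
    return float(seg[usable].sum())


def choose_projection(table: VariantTable, pops: dict, candidates: dict | None = None):
    """Grid-search projection sizes maximizing expected segregating SNPs.

    ``candidates`` maps population name -> iterable of m values; by
    default even haplotype counts from 4 up to the full (2 x diploid)
    sample size. Returns (best: dict, surface: list of (dict, mass)).
    """
    names = list(pops)
    if candidates is None:
        candidates = {}
        for p in names:
            full = 2 * len(np.asarray(pops[p]))
            candidates[p] = list(range(4, full + 1, 2)) or [full]
    import itertools
    surface = []
    best, best_mass = None, -np.inf
    for combo in itertools.product(*(candidates[p] for p in names)):
        proj = dict(zip(names, combo))
        mass = segregating_mass(table, pops, proj)
        surface.append((proj, mass))
        if mass > best_mass:
            best, best_mass = proj, mass
    return best, surface


def mask_sites_bed(table: VariantTable, bed_path) -> VariantTable:
    """Keep only sites inside the (0-based half-open) BED intervals.

    Used to restrict demographic inference to e.g. noncoding regions
    without parsing feature annotations.
    """
    import pandas as pd
    bed = pd.read_csv(bed_path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["scaffold", "start", "end"])
    keep = np.zeros(table.n_sites, dtype=bool)
    pos0 = table.sites["pos"].to_numpy() - 1
    scaf = table.sites["scaffold"].to_numpy()
    for row in bed.itertuples(index=False):
        keep |= (scaf == row.scaffold) & (pos0 >= row.start) & (pos0 < row.end)
    return table.subset_sites(keep)


def thin_sites(table: VariantTable, fraction: float = 0.01, seed: int | None = None,
               systematic: bool = False) -> VariantTable:
    """Thin sites to ``fraction``, seeded and reproducible.

    Random mode keeps an exact count ``round(fraction * n_sites)``
    sampled without replacement; ``systematic=True`` keeps every
    ``round(1/fraction)``-th site instead.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = table.n_sites
    if fraction == 1.0:
        return table
    if systematic:
        stride = max(1, int(round(1.0 / fraction)))
        keep = np.arange(0, n, stride)
    else:
        rng = np.random.default_rng(seed)
        k = int(round(fraction * n))
        keep = np.sort(rng.choice(n, size=k, replace=False))
    return table.subset_sites(keep)
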