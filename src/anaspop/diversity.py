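"""Per-site and windowed diversity / differentiation statistics.

Nucleotide diversity (pi), Weir & Cockerham (1984) variance components
and the windowed theta-hat F_ST estimator (ratio of summed components,
not mean of per-site ratios), sliding-window construction, Z
standardization, and per-sample heterozygosity summaries.

Windows are 0-based half-open [start, end) in bp; sites enter a window
via ``pos - 1``. Per-bp pi divides the summed per-site pi by the full
window length (the VCFtools ``--window-pi`` convention), so monomorphic
and uncalled bases contribute zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .variant_io import VariantTable

# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def site_allele_counts(gt_row: np.ndarray, sample_idx) -> tuple:
    """(n_haplotypes, alt_count, het_count) for one site over given samples.

    Missing genotypes are excluded: n = 2 x called samples.
    """
    g = np.asarray(gt_row)[np.asarray(sample_idx, dtype=np.intp)]
    called = g >= 0
    n = 2 * int(called.sum())
    alt = int(g[called].sum())
    het = int((g[called] == 1).sum())
    return n, alt, het


def _counts_matrix(table: VariantTable, sample_idx):
    """Vectorized (n_hap, alt, het) arrays over all sites for one sample set."""
    g = table.gt[:, np.asarray(sample_idx, dtype=np.intp)]
    called = g >= 0
    n = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    het = (g == 1).sum(axis=1)
    return n.astype(np.int64), alt.astype(np.int64), het.astype(np.int64)


def pi_site(n, alt_count):
    """Per-site nucleotide diversity 2 j (n - j) / (n (n - 1)).

    Equals the mean pairwise difference over all C(n, 2) haplotype
    pairs. Undefined (nan) for n < 2.
    """
    n = np.asarray(n, dtype=float)
    j = np.asarray(alt_count, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def wc_components(n_list, p_list, h_list):
    """Weir & Cockerham (1984) variance components (a, b, c) per site.

    Parameters are per-population arrays (length-r lists of equal-shaped
    arrays): ``n_list`` called diploid counts, ``p_list`` alternate
    allele frequencies, ``h_list`` observed heterozygote proportions.
    Components are nan where fewer than two populations have calls.

    a is the among-population component, b among individuals within
    populations, c within individuals; theta-hat = a / (a + b + c).
    """
    n = np.array([np.asarray(x, dtype=float) for x in n_list])
    p = np.array([np.asarray(x, dtype=float) for x in p_list])
    h = np.array([np.asarray(x, dtype=float) for x in h_list])
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    ok = (n >= 1).sum(axis=0) >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.sum(axis=0) / r
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1.0) / r * s2
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    bad = ~ok | (nbar <= 1)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def _site_wc(table: VariantTable, idx_a, idx_b):
    """Per-site W&C components for two sample groups of a table."""
    comps = []
    for idx in (idx_a, idx_b):
        n, alt, het = _counts_matrix(table, idx)
        n_dip = n / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.where(n > 0, n, 1), np.nan)
            hprop = np.where(n_dip > 0, het / np.where(n_dip > 0, n_dip, 1), np.nan)
        comps.append((n_dip, p, hprop))
    (n1, p1, h1), (n2, p2, h2) = comps
    return wc_components([n1, n2], [p1, p2], [h1, h2])


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(scaffold_lengths: dict, size: int = 10_000, step: int = 5_000,
                 min_scaffold: int = 10_000) -> pd.DataFrame:
    """Sliding windows [k*step, k*step + size) wholly within each scaffold.

    Scaffolds whose length is not strictly greater than ``min_scaffold``
    yield no windows. Returns a DataFrame (scaffold, start, end).
    """
    rows = []
    for scaf, length in scaffold_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive scaffold length for {scaf!r}")
        if length <= min_scaffold:
            continue
        start = 0
        while start + size <= length:
            rows.append((scaf, start, start + size))
            start += step
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def _window_site_slices(table: VariantTable, windows: pd.DataFrame):
    """Yield (window_row_index, site_index_array) pairs.

    Assumes the table is sorted; uses searchsorted per scaffold.
    """
    scaffolds = table.sites["scaffold"].to_numpy()
    pos0 = table.sites["pos"].to_numpy() - 1  # 0-based
    by_scaf = {}
    for scaf in pd.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scaf)
        order = np.argsort(pos0[idx], kind="stable")
        by_scaf[scaf] = (idx[order], pos0[idx[order]])
    for wi, row in enumerate(windows.itertuples(index=False)):
        if row.scaffold not in by_scaf:
            yield wi, np.empty(0, dtype=np.intp)
            continue
        idx, p = by_scaf[row.scaffold]
        lo = np.searchsorted(p, row.start, side="left")
        hi = np.searchsorted(p, row.end, side="left")
        yield wi, idx[lo:hi]


def window_pi(table: VariantTable, sample_idx, windows: pd.DataFrame) -> np.ndarray:
    """Per-bp pi per window for one sample set (0 for windows without SNPs)."""
    n, alt, _ = _counts_matrix(table, sample_idx)
    ps = pi_site(n, alt)
    ps = np.where(np.isfinite(ps), ps, 0.0)
    out = np.zeros(len(windows))
    lengths = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    for wi, idx in _window_site_slices(table, windows):
        out[wi] = ps[idx].sum() / lengths[wi]
    return out


def window_fst(table: VariantTable, idx_a, idx_b, windows: pd.DataFrame):
    """Windowed Weir-Cockerham theta-hat: sum(a) / sum(a+b+c) over sites.

    Returns (theta, n_sites) arrays; theta is nan where the denominator
    is zero or no informative site falls in the window.
    """
    a, b, c = _site_wc(table, idx_a, idx_b)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    num = np.where(ok, a, 0.0)
    den = np.where(ok, a + b + c, 0.0)
    theta = np.full(len(windows), np.nan)
    n_sites = np.zeros(len(windows), dtype=int)
    for wi, idx in _window_site_slices(table, windows):
        n_sites[wi] = idx.size
        d = den[idx].sum()
        if idx.size and d != 0.0:
            theta[wi] = num[idx].sum() / d
    return theta, n_sites


def global_fst(table: VariantTable, idx_a, idx_b) -> float:
    """Genome-wide ratio-of-sums theta-hat over all retained sites."""
    a, b, c = _site_wc(table, idx_a, idx_b)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    den = (a + b + c)[ok].sum()
    if not ok.any() or den == 0.0:
        return float("nan")
    return float(a[ok].sum() / den)


def zscore(values):
    """Standardize by the empirical mean/SD (ddof=1) of defined values.

    Returns (z, mu, sigma); nan inputs stay nan. sigma == 0 raises.
    """
    values = np.asarray(values, dtype=float)
    defined = values[np.isfinite(values)]
    if defined.size < 2:
        raise ValueError("need at least two defined values")
    mu = float(defined.mean())
    sigma = float(defined.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("zero standard deviation")
    return (values - mu) / sigma, mu, sigma


def sample_het_stats(table: VariantTable, grouping=None) -> pd.DataFrame:
    """Per-sample het / hom-alt genotype counts and het/hom ratio.

    With a :class:`~anaspop.variant_io.Grouping`, adds the population
    label so population means can be taken directly.
    """
    het = (table.gt == 1).sum(axis=0)
    hom = (table.gt == 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(hom > 0, het / np.where(hom > 0, hom, 1), np.nan)
    df = pd.DataFrame({
        "sample": table.samples,
        "n_het": het,
        "n_hom_alt": hom,
        "n_snp_genotypes": het + hom,
        "het_hom_ratio": ratio,
    })
    if grouping is not None:
        df["population"] = [grouping.popmap.sample_to_pop[s] for s in table.samples]
    return df
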