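"""Selective-sweep scan: joint outliers, regions, genes, diagnostic variants.

Combines windowed Z(F_ST) and the log2 diversity ratio
(pi_wild / pi_domestic) into a joint top-quantile outlier call, merges
selected windows into sweep regions, annotates regions with overlapping
genes (GFF3/BED, >= 1 bp overlap), and scans for group-diagnostic
variants (sites fixed homozygous for opposite states between two sample
groups, e.g. white- vs non-white-plumage breeds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import VariantTable
from . import diversity

logger = logging.getLogger("anaspop")


def compute_window_stats(table: VariantTable, grouping, windows: pd.DataFrame,
                         wild_group: str = "wild",
                         domestic_group: str = "domestic") -> pd.DataFrame:
    """Per-window statistics table for the sweep scan.

    Columns: scaffold, start, end, n_sites, pi_wild, pi_dom, fst, z_fst,
    log2_ratio. F_ST is Weir-Cockerham ratio-of-sums between the two
    groups; Z(F_ST) standardizes defined F_ST values by their empirical
    mean and SD; the ratio column is log2(pi_wild / pi_dom), nan where
    pi_dom is zero.
    """
    idx_w = grouping.indices(wild_group)
    idx_d = grouping.indices(domestic_group)
    snp = table.subset_sites((table.sites["var_class"] == "SNP").to_numpy())
    out = windows.copy().reset_index(drop=True)
    out["pi_wild"] = diversity.window_pi(snp, idx_w, out)
    out["pi_dom"] = diversity.window_pi(snp, idx_d, out)
    fst, n_sites = diversity.window_fst(snp, idx_w, idx_d, out)
    out["n_sites"] = n_sites
    out["fst"] = fst
    z, mu, sigma = diversity.zscore(fst)
    out["z_fst"] = z
    out.attrs["z_mu"], out.attrs["z_sigma"] = mu, sigma
    out["log2_ratio"] = pi_ratio(out["pi_wild"].to_numpy(), out["pi_dom"].to_numpy())
    # complete loss of domestic diversity with retained wild diversity:
    # the ratio is unbounded above, the extreme tail of the scan
    out["ratio_unbounded"] = (out["pi_dom"].to_numpy() == 0.0) & \
        (out["pi_wild"].to_numpy() > 0.0)
    return out


def pi_ratio(pi_wild, pi_dom):
    """log2(pi_wild / pi_dom) per window; nan (and counted in the log)
    where the domestic diversity is zero."""
    pi_wild = np.asarray(pi_wild, dtype=float)
    pi_dom = np.asarray(pi_dom, dtype=float)
    if (pi_wild < 0).any() or (pi_dom < 0).any():
        raise ValueError("diversities must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(pi_wild / pi_dom)
    undefined = pi_dom == 0.0
    if undefined.any():
        logger.info("pi_ratio: %d windows with zero domestic diversity excluded",
                    int(undefined.sum()))
    return np.where(undefined, np.nan, ratio)


def top_quantile_threshold(values, q: float):
    """Nearest-rank top-q threshold: the floor(q*N)-th largest defined value.

    Selection is inclusive (>= threshold), so ties at the threshold are
    all selected.
    """
    vals = np.asarray(values, dtype=float)
    vals = np.sort(vals[np.isfinite(vals)])
    n = vals.size
    k = int(np.floor(q * n))
    if k < 1:
        logger.warning("top_quantile_threshold: fewer than 1/q defined values (n=%d)", n)
        k = 1 if n else 0
    if k == 0:
        return np.inf
    return float(vals[n - k])


def joint_outliers(window_stats: pd.DataFrame, q: float = 0.05):
    """Windows in the top q of BOTH Z(F_ST) and log2 pi-ratio.

    Thresholds are empirical (1-q) order statistics over windows where
    the statistic is defined. Returns (selected DataFrame, thresholds
    dict with 'z_fst' and 'log2_ratio').
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    z = window_stats["z_fst"].to_numpy(dtype=float)
    r = window_stats["log2_ratio"].to_numpy(dtype=float)
    if "ratio_unbounded" in window_stats:
        unbounded = window_stats["ratio_unbounded"].to_numpy(dtype=bool)
    else:
        unbounded = np.zeros(r.shape, dtype=bool)
    thr_z = top_quantile_threshold(z, q)
    thr_r = top_quantile_threshold(r, q)
    with np.errstate(invalid="ignore"):
        sel = (z >= thr_z) & ((r >= thr_r) | unbounded)
    sel &= np.isfinite(z)
    return (window_stats.loc[sel].reset_index(drop=True),
            {"z_fst": thr_z, "log2_ratio": thr_r})


@dataclass
class SweepRegion:
    """Union of adjacent/overlapping selected windows on one scaffold."""

    scaffold: str
    start: int
    end: int
    n_windows: int
    peak_z_fst: float
    peak_log2_ratio: float
    genes: list | None = None


def merge_regions(selected: pd.DataFrame) -> list:
    """Merge overlapping or book-ended selected windows into SweepRegions,
    retaining peak statistics."""
    regions = []
    if len(selected) == 0:
        return regions
    df = selected.sort_values(["scaffold", "start"]).reset_index(drop=True)
    cur = None
    for row in df.itertuples(index=False):
        if cur is not None and row.scaffold == cur.scaffold and row.start <= cur.end:
            cur.end = max(cur.end, int(row.end))
            cur.n_windows += 1
            cur.peak_z_fst = max(cur.peak_z_fst, float(row.z_fst))
            cur.peak_log2_ratio = max(cur.peak_log2_ratio, float(row.log2_ratio))
        else:
            cur = SweepRegion(row.scaffold, int(row.start), int(row.end), 1,
                              float(row.z_fst), float(row.log2_ratio))
            regions.append(cur)
    return regions


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_track(path) -> pd.DataFrame:
    """Read gene features from GFF3 (via gffutils) or BED into a frame
    with 0-based half-open coordinates (scaffold, start, end, gene_id)."""
    path = str(path)
    rows = []
    if path.endswith((".bed", ".bed.gz")):
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        for row in bed.itertuples(index=False):
            name = str(row[3]) if len(row) > 3 else f"{row[0]}:{row[1]}-{row[2]}"
            rows.append((str(row[0]), int(row[1]), int(row[2]), name))
    else:
        import gffutils
        db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique")
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
            rows.append((feat.seqid, feat.start - 1, feat.end, gid))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "gene_id"])


def annotate_genes(regions, genes: pd.DataFrame):
    """Attach genes overlapping each region by >= 1 bp (half-open intervals).

    ``regions`` may be a list of :class:`SweepRegion` or a DataFrame of
    raw selected windows (scaffold/start/end) — both overlap modes are
    supported. Returns (regions with ``genes`` filled or a per-window
    gene-list column, sorted unique gene list). Scaffolds present in
    regions but absent from the annotation trigger a warning.
    """
    if isinstance(regions, pd.DataFrame):
        items = [SweepRegion(r.scaffold, int(r.start), int(r.end), 1,
                             float(getattr(r, "z_fst", np.nan)),
                             float(getattr(r, "log2_ratio", np.nan)))
                 for r in regions.itertuples(index=False)]
        as_frame = True
    else:
        items = regions
        as_frame = False
    by_scaf = {s: g for s, g in genes.groupby("scaffold")}
    unmatched = sorted({r.scaffold for r in items} - set(by_scaf))
    if unmatched:
        logger.warning("annotate_genes: no annotation for scaffolds %s", unmatched)
    all_genes = []
    for r in items:
        g = by_scaf.get(r.scaffold)
        if g is None:
            r.genes = []
            continue
        hit = g[(g["start"].to_numpy() < r.end) & (r.start < g["end"].to_numpy())]
        r.genes = hit["gene_id"].tolist()
        all_genes.extend(r.genes)
    unique = sorted(set(all_genes))
    if as_frame:
        out = regions.copy().reset_index(drop=True)
        out["genes"] = [r.genes for r in items]
        return out, unique
    return items, unique


# ---------------------------------------------------------------------------
# diagnostic variants
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticVariant:
    scaffold: str
    pos: int
    ref: str
    alt: str
    var_class: str
    group_a_genotype: str  # "hom_alt" or "hom_ref"
    group_b_genotype: str


def diagnostic_variants(table: VariantTable, group_a_idx, group_b_idx,
                        min_called: int = 1) -> list:
    """Variants fixed homozygous for opposite states between two groups.

    Every called group-A sample must be homozygous for one allele and
    every called group-B sample homozygous for the other, with at least
    ``min_called`` called samples per group. Heterozygotes anywhere
    disqualify a site.
    """
    ia = np.asarray(group_a_idx, dtype=np.intp)
    ib = np.asarray(group_b_idx, dtype=np.intp)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be non-empty")
    ga, gb = table.gt[:, ia], table.gt[:, ib]
    ca, cb = ga >= 0, gb >= 0
    na, nb = ca.sum(axis=1), cb.sum(axis=1)
    enough = (na >= min_called) & (nb >= min_called)

    def fixed(g, c, code):
        return (np.where(c, g, code) == code).all(axis=1)

    a_alt = fixed(ga, ca, 2)
    a_ref = fixed(ga, ca, 0)
    b_alt = fixed(gb, cb, 2)
    b_ref = fixed(gb, cb, 0)
    hit = enough & ((a_alt & b_ref) | (a_ref & b_alt))
    out = []
    for i in np.flatnonzero(hit):
        row = table.sites.iloc[i]
        alt_in_a = bool(a_alt[i] and b_ref[i])
        out.append(DiagnosticVariant(
            scaffold=row["scaffold"], pos=int(row["pos"]),
            ref=row["ref"], alt=row["alt"], var_class=row["var_class"],
            group_a_genotype="hom_alt" if alt_in_a else "hom_ref",
            group_b_genotype="hom_ref" if alt_in_a else "hom_alt",
        ))
    return out
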