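"""Variant and population-map I/O.

Reads multi-sample VCF v4.2 into the in-memory table all downstream
statistics consume (a pandas site frame plus a dense int8 genotype
matrix), writes tables back to VCF, classifies variants into SNPs and
small INDELs (1-50 bp), and validates sample -> population -> group
assignments.

Conventions
-----------
* Genotypes are coded 0 (hom ref), 1 (het), 2 (hom alt), -1 (missing).
  Half-calls such as ``0/.`` are treated as fully missing.
* Coordinates are 1-based in VCF I/O (``pos`` column); window logic
  elsewhere uses 0-based half-open intervals via ``pos - 1``.
* Multiallelic records are split into one biallelic record per ALT;
  alleles belonging to a non-focal ALT are recoded as reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF
import pysam

logger = logging.getLogger("anaspop")

#: QC annotations carried as site-frame columns (VCF INFO names).
QC_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP")

SITE_COLUMNS = ("scaffold", "pos", "ref", "alt", "var_class", "indel_len", "QUAL") + QC_FIELDS

#: Largest INDEL length (bp) retained by :func:`classify_variants`.
MAX_INDEL_LEN = 50


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; names the offending file/record."""


@dataclass
class VariantTable:
    """Sites plus per-sample genotypes, sorted by (scaffold, pos).

    Attributes
    ----------
    samples : list of str
        Sample names; column order of all per-sample matrices.
    sites : pandas.DataFrame
        One row per biallelic variant with columns ``SITE_COLUMNS``.
    gt : ndarray of int8, shape (n_sites, n_samples)
        Genotype codes 0/1/2, -1 for missing.
    ad_ref, ad_alt : ndarray of int32 or None
        Per-sample ref/alt allele depths (-1 where absent).
    sample_dp : ndarray of int32 or None
        Per-sample total read depth (-1 where absent).
    scaffold_lengths : dict
        Contig name -> length in bp.
    """

    samples: list
    sites: pd.DataFrame
    gt: np.ndarray
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    sample_dp: np.ndarray | None = None
    scaffold_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sites) != self.gt.shape[0]:
            raise ValueError("sites and gt row counts differ")
        if self.gt.shape[1] != len(self.samples):
            raise ValueError("gt column count does not match samples")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_sites(self, mask) -> "VariantTable":
        """Return a new table keeping rows where ``mask`` is True (or an index array)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            gt=self.gt[idx],
            ad_ref=None if self.ad_ref is None else self.ad_ref[idx],
            ad_alt=None if self.ad_alt is None else self.ad_alt[idx],
            sample_dp=None if self.sample_dp is None else self.sample_dp[idx],
        )

    def subset_samples(self, names) -> "VariantTable":
        missing = [s for s in names if s not in self.samples]
        if missing:
            raise ValueError(f"unknown samples: {missing}")
        cols = np.array([self.samples.index(s) for s in names])
        return replace(
            self,
            samples=list(names),
            gt=self.gt[:, cols],
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, cols],
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, cols],
            sample_dp=None if self.sample_dp is None else self.sample_dp[:, cols],
        )

    def sort(self) -> "VariantTable":
        order = np.lexsort((self.sites["pos"].to_numpy(), self.sites["scaffold"].to_numpy()))
        return self.subset_sites(order)

    def equals(self, other: "VariantTable", rtol: float = 1e-6, atol: float = 1e-6) -> bool:
        """Field-level equality; float QC columns compared with tolerance."""
        if self.samples != other.samples or self.n_sites != other.n_sites:
            return False
        if not np.array_equal(self.gt, other.gt):
            return False
        for col in ("scaffold", "pos", "ref", "alt", "var_class", "indel_len"):
            if not self.sites[col].tolist() == other.sites[col].tolist():
                return False
        for col in ("QUAL",) + QC_FIELDS:
            a = self.sites[col].to_numpy(dtype=float)
            b = other.sites[col].to_numpy(dtype=float)
            if not np.allclose(a, b, rtol=rtol, atol=atol, equal_nan=True):
                return False
        for x, y in ((self.ad_ref, other.ad_ref), (self.ad_alt, other.ad_alt),
                     (self.sample_dp, other.sample_dp)):
            if (x is None) != (y is None):
                return False
            if x is not None and not np.array_equal(x, y):
                return False
        return self.scaffold_lengths == other.scaffold_lengths


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """sample -> population plus population -> group labels.

    ``pop_groups[pop]`` is a tuple of group labels, e.g. a production
    type (wild / meat / egg / dual-purpose) and optionally a plumage
    class (white / non-white).
    """

    sample_to_pop: dict
    pop_groups: dict

    def __post_init__(self):
        missing = set(self.sample_to_pop.values()) - set(self.pop_groups)
        if missing:
            raise ValueError(f"populations without group labels: {sorted(missing)}")

    @property
    def populations(self) -> list:
        seen = []
        for p in self.sample_to_pop.values():
            if p not in seen:
                seen.append(p)
        return seen

    @property
    def group_labels(self) -> list:
        seen = []
        for groups in self.pop_groups.values():
            for g in groups:
                if g not in seen:
                    seen.append(g)
        return seen

    def pops_in_group(self, group) -> list:
        return [p for p in self.populations if group in self.pop_groups.get(p, ())]

    def samples_in_pop(self, pop) -> list:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def samples_in_group(self, group) -> list:
        pops = set(self.pops_in_group(group))
        return [s for s, p in self.sample_to_pop.items() if p in pops]


def read_popmap(path) -> PopulationMap:
    """Read a 3-column TSV: sample, population, comma-separated group labels."""
    sample_to_pop, pop_groups = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            sample, pop = parts[0], parts[1]
            groups = tuple(parts[2].split(",")) if len(parts) > 2 and parts[2] else ()
            if sample in sample_to_pop:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            sample_to_pop[sample] = pop
            prior = pop_groups.setdefault(pop, groups)
            if prior != groups:
                raise ValueError(f"{path}:{lineno}: inconsistent groups for population {pop!r}")
    return PopulationMap(sample_to_pop, pop_groups)


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.sample_to_pop.items():
            fh.write(f"{sample}\t{pop}\t{','.join(popmap.pop_groups[pop])}\n")


@dataclass
class Grouping:
    """Validated per-population / per-group sample index lists for a table."""

    popmap: PopulationMap
    pop_indices: dict
    group_indices: dict

    def indices(self, label) -> np.ndarray:
        """Indices for a population or group label (populations win on clash)."""
        if label in self.pop_indices:
            return self.pop_indices[label]
        if label in self.group_indices:
            return self.group_indices[label]
        raise KeyError(f"unknown population or group: {label!r}")


def attach_populations(table: VariantTable, popmap: PopulationMap) -> Grouping:
    """Validate that the map covers the table and build index lists.

    Raises
    ------
    ValueError
        If a table sample is missing from the map, or a mapped
        population has no samples in the table.
    """
    uncovered = [s for s in table.samples if s not in popmap.sample_to_pop]
    if uncovered:
        raise ValueError(f"samples missing from population map: {uncovered}")
    sample_idx = {s: i for i, s in enumerate(table.samples)}
    pop_indices = {}
    for pop in popmap.populations:
        idx = np.array([sample_idx[s] for s in popmap.samples_in_pop(pop) if s in sample_idx],
                       dtype=np.intp)
        if idx.size == 0:
            raise ValueError(f"population {pop!r} has no samples in the table")
        pop_indices[pop] = idx
    group_indices = {}
    for g in popmap.group_labels:
        idx = np.array([sample_idx[s] for s in popmap.samples_in_group(g) if s in sample_idx],
                       dtype=np.intp)
        group_indices[g] = idx
    return Grouping(popmap, pop_indices, group_indices)


def read_scaffold_lengths(path) -> dict:
    """Read scaffold lengths from a 2-column TSV (name, length in bp)."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = int(parts[1])
    return out


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _info_float(variant, key):
    v = variant.INFO.get(key)
    return float(v) if v is not None else np.nan


def read_vcf(path, sample_subset=None, split_multiallelic: bool = True) -> VariantTable:
    """Read a VCF v4.2 into a :class:`VariantTable`.

    Parameters
    ----------
    sample_subset : sequence of str, optional
        Restrict to these samples (order preserved). Unknown names raise.
    split_multiallelic : bool
        Split multiallelic records into biallelic ones per ALT; if False,
        multiallelic records are rejected with an error.
    """
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in all_samples]
        if unknown:
            raise ValueError(f"samples not in VCF {path}: {unknown}")
        keep_cols = np.array([all_samples.index(s) for s in sample_subset])
        samples = list(sample_subset)
    else:
        keep_cols = None
        samples = all_samples

    scaffold_lengths = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        scaffold_lengths[name] = int(length)

    rows, gts, adr, ada, sdp = [], [], [], [], []
    any_ad = False
    any_dp = False
    for variant in vcf:
        alts = variant.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and not split_multiallelic:
            raise VcfParseError(
                f"{path}: multiallelic record at {variant.CHROM}:{variant.POS} "
                "(re-run with split_multiallelic=True)")
        genos = variant.genotypes  # [[a, b, phased], ...]
        try:
            ad = variant.format("AD")
        except Exception:
            ad = None
        try:
            dp = variant.format("DP")
        except Exception:
            dp = None
        for k, alt in enumerate(alts, start=1):
            codes = np.empty(len(all_samples), dtype=np.int8)
            for i, g in enumerate(genos):
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    codes[i] = -1
                else:
                    codes[i] = (1 if a == k else 0) + (1 if b == k else 0)
            row = {
                "scaffold": variant.CHROM,
                "pos": int(variant.POS),
                "ref": variant.REF,
                "alt": alt,
                "var_class": "",
                "indel_len": 0,
                "QUAL": variant.QUAL if variant.QUAL is not None else np.nan,
            }
            for f in QC_FIELDS:
                row[f] = _info_float(variant, f)
            rows.append(row)
            if keep_cols is not None:
                codes = codes[keep_cols]
            gts.append(codes)
            if ad is not None:
                any_ad = True
                ref_d = ad[:, 0].astype(np.int32)
                alt_d = ad[:, k].astype(np.int32) if ad.shape[1] > k else np.full(len(all_samples), -1, np.int32)
            else:
                ref_d = np.full(len(all_samples), -1, np.int32)
                alt_d = np.full(len(all_samples), -1, np.int32)
            if dp is not None:
                any_dp = True
                d = dp.reshape(-1).astype(np.int32)
            else:
                d = np.full(len(all_samples), -1, np.int32)
            # htslib encodes missing integers as INT32_MIN; normalize to -1
            ref_d = np.where(ref_d < 0, -1, ref_d).astype(np.int32)
            alt_d = np.where(alt_d < 0, -1, alt_d).astype(np.int32)
            d = np.where(d < 0, -1, d).astype(np.int32)
            if keep_cols is not None:
                ref_d, alt_d, d = ref_d[keep_cols], alt_d[keep_cols], d[keep_cols]
            adr.append(ref_d)
            ada.append(alt_d)
            sdp.append(d)
    vcf.close()

    n = len(rows)
    sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS)) if n else pd.DataFrame(
        {c: pd.Series(dtype=("int64" if c in ("pos", "indel_len") else
                             "float64" if c in ("QUAL",) + QC_FIELDS else "object"))
         for c in SITE_COLUMNS})
    gt = np.vstack(gts).astype(np.int8) if n else np.zeros((0, len(samples)), np.int8)
    table = VariantTable(
        samples=samples,
        sites=sites,
        gt=gt,
        ad_ref=np.vstack(adr) if (n and any_ad) else None,
        ad_alt=np.vstack(ada) if (n and any_ad) else None,
        sample_dp=np.vstack(sdp) if (n and any_dp) else None,
        scaffold_lengths=scaffold_lengths,
    )
    table, _ = classify_variants(table)
    return table.sort()


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

def write_vcf(table: VariantTable, path) -> None:
    """Write a sorted, header-complete VCF v4.2 readable by :func:`read_vcf`."""
    header = pysam.VariantHeader()
    for f, typ, desc in (
        ("QD", "Float", "Variant confidence by depth"),
        ("FS", "Float", "Phred-scaled strand-bias Fisher p"),
        ("MQ", "Float", "RMS mapping quality"),
        ("MQRankSum", "Float", "Mapping-quality rank-sum Z"),
        ("ReadPosRankSum", "Float", "Read-position rank-sum Z"),
        ("DP", "Integer", "Combined read depth"),
    ):
        header.add_meta("INFO", items=[("ID", f), ("Number", "1"), ("Type", typ),
                                       ("Description", desc)])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                                     ("Description", "Allele depths")])
    header.add_meta("FORMAT", items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
                                     ("Description", "Read depth")])
    contigs = dict(table.scaffold_lengths)
    for scaf in pd.unique(table.sites["scaffold"]):
        if scaf not in contigs:
            contigs[scaf] = int(table.sites.loc[table.sites.scaffold == scaf, "pos"].max()) + 1000
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for s in table.samples:
        header.add_sample(s)

    table = table.sort()
    gt_alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(table.n_sites):
            row = table.sites.iloc[i]
            rec = out.new_record(
                contig=row["scaffold"],
                start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
            )
            if np.isfinite(row["QUAL"]):
                rec.qual = float(row["QUAL"])
            for f in QC_FIELDS:
                v = row[f]
                if isinstance(v, float) and not np.isfinite(v):
                    continue
                rec.info[f] = int(v) if f == "DP" else float(v)
            for j, s in enumerate(table.samples):
                rec.samples[s]["GT"] = gt_alleles[int(table.gt[i, j])]
                if table.ad_ref is not None and table.ad_ref[i, j] >= 0:
                    rec.samples[s]["AD"] = (int(table.ad_ref[i, j]), int(table.ad_alt[i, j]))
                if table.sample_dp is not None and table.sample_dp[i, j] >= 0:
                    rec.samples[s]["DP"] = int(table.sample_dp[i, j])
            out.write(rec)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_variants(table: VariantTable):
    """Assign ``var_class``/``indel_len`` and drop symbolic or oversized alleles.

    A record is a SNP when both alleles are single bases, otherwise an
    INDEL with signed length ``len(alt) - len(ref)``. INDELs longer than
    ``MAX_INDEL_LEN`` (50 bp) are dropped and counted. Symbolic alleles
    (e.g. ``<DEL>``) are rejected with an error.

    Returns
    -------
    (VariantTable, dict)
        Classified table and a report ``{"snp": int, "indel": int,
        "dropped_long_indel": int}``.
    """
    ref = table.sites["ref"].astype(str)
    alt = table.sites["alt"].astype(str)
    symbolic = ref.str.contains("[<>*\\[\\]]", regex=True) | alt.str.contains("[<>*\\[\\]]", regex=True)
    if symbolic.any():
        pos = table.sites.loc[symbolic, ["scaffold", "pos"]].iloc[0]
        raise ValueError(f"symbolic allele at {pos['scaffold']}:{pos['pos']} not supported")
    if (ref.str.len() == 0).any() or (alt.str.len() == 0).any():
        raise ValueError("empty allele string")
    indel_len = (alt.str.len() - ref.str.len()).astype(int)
    is_snp = (ref.str.len() == 1) & (alt.str.len() == 1)
    sites = table.sites.copy()
    sites["var_class"] = np.where(is_snp, "SNP", "INDEL")
    sites["indel_len"] = np.where(is_snp, 0, indel_len)
    out = replace(table, sites=sites)
    too_long = (~is_snp) & (indel_len.abs() > MAX_INDEL_LEN)
    n_long = int(too_long.sum())
    if n_long:
        logger.info("classify_variants: dropping %d INDELs longer than %d bp",
                    n_long, MAX_INDEL_LEN)
        out = out.subset_sites(~too_long.to_numpy())
    report = {
        "snp": int((out.sites["var_class"] == "SNP").sum()),
        "indel": int((out.sites["var_class"] == "INDEL").sum()),
        "dropped_long_indel": n_long,
    }
    return out, report
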