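"""Variant quality-control filters.

Implements the hard-filter stage of a GATK-style short-variant pipeline:
annotation thresholds for SNPs and INDELs, removal of dense SNP clusters
(false positives from misalignment), an allele-depth consistency rule,
and the minor-allele-frequency / call-rate site filter applied before
population-structure analyses.

Every filter returns ``(table, FilterReport)`` and is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .variant_io import VariantTable

logger = logging.getLogger("anaspop")

#: SNP hard-filter thresholds: annotation -> (op, value); all must hold strictly.
SNP_HARD_CRITERIA = {
    "QUAL": (">", 30.0),
    "QD": (">", 5.0),
    "FS": ("<", 60.0),
    "MQ": (">", 40.0),
    "MQRankSum": (">", -12.5),
    "ReadPosRankSum": (">", -8.0),
}

#: INDEL hard-filter thresholds.
INDEL_HARD_CRITERIA = {
    "QUAL": (">", 30.0),
    "QD": (">", 5.0),
    "FS": ("<", 200.0),
    "ReadPosRankSum": (">", -20.0),
}


@dataclass
class FilterReport:
    """Ordered per-filter tested/passed/failed counts."""

    entries: list = field(default_factory=list)  # (name, tested, passed, failed)

    def add(self, name, tested, passed):
        self.entries.append((name, int(tested), int(passed), int(tested) - int(passed)))
        return self

    def extend(self, other: "FilterReport"):
        self.entries.extend(other.entries)
        return self

    @property
    def names(self):
        return [e[0] for e in self.entries]

    def counts(self, name):
        for n, tested, passed, failed in self.entries:
            if n == name:
                return {"tested": tested, "passed": passed, "failed": failed}
        raise KeyError(name)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("filter\ttested\tpassed\tfailed\n")
            for n, t, p, f in self.entries:
                fh.write(f"{n}\t{t}\t{p}\t{f}\n")

    def __str__(self):
        return "; ".join(f"{n}: {p}/{t} passed" for n, t, p, _ in self.entries)


def _hard_filter(table, criteria, var_class, name, drop_missing_annotation):
    is_target = (table.sites["var_class"] == var_class).to_numpy()
    keep = np.ones(table.n_sites, dtype=bool)
    for col, (op, threshold) in criteria.items():
        vals = table.sites[col].to_numpy(dtype=float)
        ok = vals > threshold if op == ">" else vals < threshold
        missing = ~np.isfinite(vals)
        if missing.any() and is_target.any():
            n_miss = int((missing & is_target).sum())
            if n_miss:
                logger.warning("%s: %d records lack %s (%s)", name, n_miss, col,
                               "dropped" if drop_missing_annotation else "kept")
        ok = np.where(missing, not drop_missing_annotation, ok)
        keep &= ok
    final = ~is_target | keep
    report = FilterReport().add(name, is_target.sum(), (is_target & keep).sum())
    return table.subset_sites(final), report


def filter_snps_hard(table: VariantTable, drop_missing_annotation: bool = False):
    """Hard-filter SNPs: QUAL>30, QD>5, FS<60, MQ>40, MQRankSum>-12.5,
    ReadPosRankSum>-8 (all strict). Non-SNP records pass through untouched.

    Records lacking an annotation pass that criterion by default
    (``drop_missing_annotation=True`` inverts this).
    """
    return _hard_filter(table, SNP_HARD_CRITERIA, "SNP", "snp_hard", drop_missing_annotation)


def filter_indels_hard(table: VariantTable, drop_missing_annotation: bool = False):
    """Hard-filter INDELs: QUAL>30, QD>5, FS<200, ReadPosRankSum>-20 (strict)."""
    return _hard_filter(table, INDEL_HARD_CRITERIA, "INDEL", "indel_hard",
                        drop_missing_annotation)


def filter_snp_clusters(table: VariantTable, window_bp: int = 10, max_snps: int = 3):
    """Remove SNPs lying in clusters of more than ``max_snps`` within any
    ``window_bp``-bp interval (sliding, per scaffold).

    A SNP is removed iff it belongs to a run of ``max_snps + 1``
    position-consecutive SNPs spanning at most ``window_bp`` bases
    (positions within ``window_bp - 1`` of each other), which is
    equivalent to membership in some ``window_bp`` interval holding more
    than ``max_snps`` SNPs. INDELs are ignored by the cluster rule.
    """
    is_snp = (table.sites["var_class"] == "SNP").to_numpy()
    drop = np.zeros(table.n_sites, dtype=bool)
    k = max_snps + 1
    snp_idx = np.flatnonzero(is_snp)
    scaffolds = table.sites["scaffold"].to_numpy()
    positions = table.sites["pos"].to_numpy()
    for scaf in np.unique(scaffolds[snp_idx]) if snp_idx.size else []:
        idx = snp_idx[scaffolds[snp_idx] == scaf]
        pos = np.sort(positions[idx])
        order = np.argsort(positions[idx], kind="stable")
        if pos.size < k:
            continue
        span = pos[k - 1:] - pos[:pos.size - k + 1]
        mark = np.zeros(pos.size, dtype=bool)
        for j in np.flatnonzero(span <= window_bp - 1):
            mark[j:j + k] = True
        drop[idx[order[mark]]] = True
    report = FilterReport().add("snp_cluster", is_snp.sum(), is_snp.sum() - drop.sum())
    return table.subset_sites(~drop), report


def filter_allele_depth(table: VariantTable, per_sample: bool = False):
    """Remove variants whose alternate-allele depth is less than half the
    read depth, aggregated over carrier samples.

    Carriers are samples with a het or hom-alt genotype. The default
    (site-aggregate) rule removes a variant when
    ``sum(AD_alt over carriers) < 0.5 * sum(DP over carriers)``; the
    boundary (exactly half) is kept. ``per_sample=True`` instead removes
    the variant if any single carrier violates the rule. Sites lacking
    AD/DP pass through with a warning.
    """
    n = table.n_sites
    if table.ad_alt is None or table.sample_dp is None:
        logger.warning("filter_allele_depth: table lacks AD/DP; all %d sites passed", n)
        return table.subset_sites(np.ones(n, bool)), FilterReport().add("allele_depth", n, n)
    carrier = (table.gt == 1) | (table.gt == 2)
    have = carrier & (table.ad_alt >= 0) & (table.sample_dp >= 0)
    alt_d = np.where(have, table.ad_alt, 0)
    dp = np.where(have, table.sample_dp, 0)
    if per_sample:
        bad = (have & (alt_d * 2 < dp)).any(axis=1)
    else:
        bad = alt_d.sum(axis=1) * 2 < dp.sum(axis=1)
    no_data = ~have.any(axis=1)
    if no_data.any():
        logger.warning("filter_allele_depth: %d sites without carrier AD/DP passed through",
                       int(no_data.sum()))
    keep = no_data | ~bad
    return table.subset_sites(keep), FilterReport().add("allele_depth", n, keep.sum())


def filter_structure_sites(table: VariantTable, maf_gt: float = 0.1,
                           call_rate_gt: float = 0.9):
    """Site filter for structure analyses: keep SNPs with minor allele
    frequency strictly above ``maf_gt`` and genotype call rate strictly
    above ``call_rate_gt`` across all samples. Non-SNP records are
    excluded from the output.
    """
    is_snp = (table.sites["var_class"] == "SNP").to_numpy()
    called = table.gt >= 0
    n_called = called.sum(axis=1)
    n_hap = 2 * n_called
    alt = np.where(called, table.gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(alt, n_hap - alt) / np.where(n_hap > 0, n_hap, 1)
        call_rate = n_called / table.n_samples
    keep = is_snp & (n_hap > 0) & (maf > maf_gt) & (call_rate > call_rate_gt)
    report = FilterReport().add("structure_sites", is_snp.sum(), keep.sum())
    return table.subset_sites(keep), report


def apply_filters(table: VariantTable, steps=("snp_hard", "indel_hard", "cluster", "depth")):
    """Apply filters in order, chaining reports (tested(k+1) = passed set of k)."""
    fns = {
        "snp_hard": filter_snps_hard,
        "indel_hard": filter_indels_hard,
        "cluster": filter_snp_clusters,
        "depth": filter_allele_depth,
        "structure": filter_structure_sites,
    }
    report = FilterReport()
    for step in steps:
        table, rep = fns[step](table)
        report.extend(rep)
        logger.info("filter %s: %s", step, rep)
    return table, report
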