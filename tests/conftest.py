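import numpy as np
import pandas as pd
import pytest

from anaspop import coalescent_sim as cs
from anaspop.variant_io import VariantTable, PopulationMap, SITE_COLUMNS


def make_table(gt, positions=None, scaffold="scaf1", samples=None,
               var_class=None, ref_alt=None, qc=None, scaffold_length=None,
               ad=None, dp=None):
    """Build a small VariantTable by hand for unit tests."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    positions = positions if positions is not None else np.arange(1, n_sites + 1) * 100
    rows = []
    for i in range(n_sites):
        ref, alt = (ref_alt[i] if ref_alt else ("A", "G"))
        vc = var_class[i] if var_class else ("SNP" if len(ref) == len(alt) == 1 else "INDEL")
        row = {"scaffold": scaffold if isinstance(scaffold, str) else scaffold[i],
               "pos": int(positions[i]), "ref": ref, "alt": alt,
               "var_class": vc, "indel_len": len(alt) - len(ref) if vc == "INDEL" else 0,
               "QUAL": 100.0, "QD": 20.0, "FS": 5.0, "MQ": 55.0,
               "MQRankSum": 0.0, "ReadPosRankSum": 0.0, "DP": 100.0}
        if qc:
            row.update(qc[i])
        rows.append(row)
    max_pos = int(max(positions)) if len(positions) else 0
    scafs = {scaffold: (scaffold_length or max_pos + 1000)} \
        if isinstance(scaffold, str) else \
        {s: max_pos + 1000 for s in set(scaffold)}
    return VariantTable(
        samples=samples,
        sites=pd.DataFrame(rows, columns=list(SITE_COLUMNS)),
        gt=gt,
        ad_ref=None if ad is None else np.asarray(ad[0], dtype=np.int32),
        ad_alt=None if ad is None else np.asarray(ad[1], dtype=np.int32),
        sample_dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        scaffold_lengths=scafs,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate full-design cohort (78 samples, 10 x 50 kb scaffolds)."""
    cfg = cs.SimulationConfig(seed=42, n_scaffolds=10, scaffold_length=50_000)
    table, truth = cs.simulate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_grouping(small_cohort):
    from anaspop.variant_io import attach_populations
    cfg, table, _ = small_cohort
    return attach_populations(table, cfg.popmap())


@pytest.fixture
def two_pop_map():
    return PopulationMap(
        {"s0": "A", "s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "B"},
        {"A": ("left",), "B": ("right",)},
    )
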