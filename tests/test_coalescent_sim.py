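import hashlib
import random

import numpy as np
import pytest

import anaspop
from anaspop import coalescent_sim as cs
from anaspop import variant_io
from anaspop.demography import DemographicModel, SizeChange, Split


def one_pop(nu=1.0):
    return DemographicModel(sampled=("p",), initial_sizes={"p": nu})


def split_model(T, nu=1.0, M=0.0):
    return DemographicModel(
        sampled=("p", "q"),
        initial_sizes={"p": nu, "q": nu},
        events=(Split(T, "p", "anc", nu), Split(T, "q", "anc")),
        migration={("p", "q"): M, ("q", "p"): M},
    )


class TestGenealogy:
    def test_pairwise_tmrca_expectation(self):
        rng = random.Random(1)
        nu = 0.7
        ts = [cs.simulate_genealogy(one_pop(nu), {"p": 2}, rng).tmrca
              for _ in range(5000)]
        se = np.std(ts) / np.sqrt(len(ts))
        assert abs(np.mean(ts) - nu) < 3 * se

    def test_no_coalescence_before_split_without_migration(self):
        rng = random.Random(2)
        model = split_model(T=0.5)
        for _ in range(200):
            g = cs.simulate_genealogy(model, {"p": 1, "q": 1}, rng)
            assert g.tmrca >= 0.5

    def test_island_model_tmrca_matches_msprime(self):
        import msprime
        nu, M = 1.0, 2.0
        model = DemographicModel(
            sampled=("p", "q"),
            initial_sizes={"p": nu, "q": nu},
            events=(Split(50.0, "p", "anc", nu), Split(50.0, "q", "anc")),
            migration={("p", "q"): M, ("q", "p"): M},
        )
        rng = random.Random(3)
        ours = [cs.simulate_genealogy(model, {"p": 1, "q": 1}, rng).tmrca
                for _ in range(4000)]
        dem = msprime.Demography()
        # msprime haploid model: pair coalescence rate 1/N per generation,
        # so N = nu makes one generation = one scaled time unit; the
        # backwards per-lineage hop rate is M on both sides
        dem.add_population(name="p", initial_size=nu)
        dem.add_population(name="q", initial_size=nu)
        dem.set_migration_rate("p", "q", M)
        dem.set_migration_rate("q", "p", M)
        theirs = [
            next(ts.trees()).time(ts.first().root)
            for ts in msprime.sim_ancestry(
                samples={"p": 1, "q": 1}, demography=dem, ploidy=1,
                num_replicates=4000, random_seed=11)
        ]
        se = np.hypot(np.std(ours) / np.sqrt(len(ours)),
                      np.std(theirs) / np.sqrt(len(theirs)))
        assert abs(np.mean(ours) - np.mean(theirs)) < 3 * se

    def test_branch_sfs_matches_msprime_island_model(self):
        import msprime
        nu, M, n = 1.0, 1.0, 4
        model = split_model(T=60.0, nu=nu, M=M)
        ours = cs.branch_sfs(model, {"p": n, "q": n}, 8000, seed=5)
        dem = msprime.Demography()
        dem.add_population(name="p", initial_size=nu)
        dem.add_population(name="q", initial_size=nu)
        dem.set_migration_rate("p", "q", M)
        dem.set_migration_rate("q", "p", M)
        acc = np.zeros((n + 1, n + 1))
        reps = msprime.sim_ancestry(samples={"p": n, "q": n}, demography=dem,
                                    ploidy=1, num_replicates=8000, random_seed=4)
        for ts in reps:
            acc += ts.allele_frequency_spectrum(
                sample_sets=[list(range(n)), list(range(n, 2 * n))],
                mode="branch", polarised=True, span_normalise=True)
        theirs = acc / 8000
        a = ours / ours.sum()
        b = theirs / theirs.sum()
        assert 0.5 * np.abs(a - b).sum() < 0.02  # total-variation distance


class TestMutations:
    def test_zero_theta_gives_no_variants(self):
        g = cs.simulate_genealogy(one_pop(), {"p": 4}, random.Random(1))
        assert cs.drop_mutations(g, 0.0, 1000, random.Random(1)) == []

    def test_pairwise_diversity_matches_theta(self):
        theta, L = 0.01, 2000
        rng = random.Random(8)
        diffs = []
        for _ in range(600):
            g = cs.simulate_genealogy(one_pop(), {"p": 2}, rng)
            muts = cs.drop_mutations(g, theta, L, rng)
            diffs.append(len(muts) / L)
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - theta) < 3 * se

    def test_between_population_divergence_closed_form(self):
        # d_xy per site = theta + T * theta (scaled: E[T_between] = nu + T)
        theta, L, T = 0.01, 2000, 1.5
        model = split_model(T)
        rng = random.Random(9)
        dxy = []
        for _ in range(600):
            g = cs.simulate_genealogy(model, {"p": 1, "q": 1}, rng)
            muts = cs.drop_mutations(g, theta, L, rng)
            dxy.append(len(muts) / L)
        expected = theta * (1 + T)  # 2 * (nu/... ) pairwise branch = 2*E[T]
        se = np.std(dxy) / np.sqrt(len(dxy))
        assert abs(np.mean(dxy) - expected) < 3 * se

    def test_infinite_sites_positions_distinct(self):
        g = cs.simulate_genealogy(one_pop(), {"p": 6}, random.Random(3))
        muts = cs.drop_mutations(g, 5.0, 100, random.Random(3))
        positions = [p for p, _ in muts]
        assert len(positions) == len(set(positions))
        assert positions == sorted(positions)


class TestCohort:
    def test_structural_contract(self):
        cfg = cs.SimulationConfig(
            seed=1, populations={"A": 2, "B": 2},
            pop_deme={"A": "wild", "B": "meat"},
            pop_groups={"A": ("wild",), "B": ("meat", "domestic")},
            model=split_model(0.05, nu=0.5),
            n_scaffolds=1, scaffold_length=100_000, segment_bp=10_000)
        cfg.pop_deme = {"A": "p", "B": "q"}
        table, truth = cs.simulate_cohort(cfg)
        assert table.n_samples == 4
        assert len(truth.windows) == 10
        assert all(w["label"] == "neutral" for w in truth.windows)
        assert table.n_sites >= 0

    def test_zero_missingness(self):
        cfg = cs.SimulationConfig(seed=2, n_scaffolds=1, scaffold_length=20_000,
                                  missingness=0.0)
        table, _ = cs.simulate_cohort(cfg)
        assert (table.gt >= 0).all()

    def test_same_seed_byte_identical_vcf(self, tmp_path):
        paths = []
        for name in ("a", "b"):
            cfg = cs.SimulationConfig(seed=77, n_scaffolds=2, scaffold_length=20_000)
            table, _ = cs.simulate_cohort(cfg)
            p = tmp_path / f"{name}.vcf"
            variant_io.write_vcf(table, p)
            paths.append(hashlib.sha256(p.read_bytes()).hexdigest())
        assert paths[0] == paths[1]

    def test_wild_diversity_exceeds_domestic(self, small_cohort, small_grouping):
        import pandas as pd
        from anaspop import diversity
        _, table, _ = small_cohort
        wins = diversity.make_windows(table.scaffold_lengths)
        snp = table.subset_sites((table.sites["var_class"] == "SNP").to_numpy())
        pi_w = diversity.window_pi(snp, small_grouping.indices("wild"), wins)
        pi_d = diversity.window_pi(snp, small_grouping.indices("domestic"), wins)
        assert pi_w.mean() / pi_d.mean() > 1.0

    def test_qc_annotations_exercisable_by_filters(self, small_cohort):
        from anaspop import filters
        _, table, _ = small_cohort
        out, _ = filters.filter_snps_hard(table)
        n_snp = (table.sites["var_class"] == "SNP").sum()
        assert (out.sites["var_class"] == "SNP").sum() == n_snp  # passing ranges
        cfg = cs.SimulationConfig(seed=6, n_scaffolds=1, scaffold_length=20_000,
                                  qc_fail_fraction=0.5)
        bad_table, _ = cs.simulate_cohort(cfg)
        filtered, rep = filters.apply_filters(bad_table,
                                              ["snp_hard", "indel_hard"])
        assert filtered.n_sites < bad_table.n_sites

    def test_indel_lengths_one_bp_predominant(self):
        cfg = cs.SimulationConfig(seed=3, n_scaffolds=4, scaffold_length=50_000,
                                  indel_fraction=0.5)
        table, _ = cs.simulate_cohort(cfg)
        lens = table.sites.loc[table.sites.var_class == "INDEL", "indel_len"].abs()
        assert len(lens) > 50
        assert (lens == 1).mean() > (lens == 2).mean()
        assert lens.max() <= 50


class TestSweepInjection:
    def test_factor_one_is_neutral_identity(self):
        base = cs.SimulationConfig(seed=21, n_scaffolds=1, scaffold_length=30_000)
        t1, _ = cs.simulate_cohort(base)
        cfg = cs.inject_sweep(base, cs.SweepSpec("scaffold_1", 0, 10_000, 1.0))
        t2, truth2 = cs.simulate_cohort(cfg)
        assert t1.equals(t2)
        assert truth2.windows[0]["label"] == "neutral"

    def test_sweep_reduces_domestic_diversity(self):
        from anaspop import diversity
        from scipy.stats import mannwhitneyu
        cfg = cs.SimulationConfig(
            seed=22, n_scaffolds=5, scaffold_length=100_000,
            sweeps=[cs.SweepSpec(f"scaffold_{i}", 0, 50_000, 10.0)
                    for i in range(1, 6)])
        table, truth = cs.simulate_cohort(cfg)
        grouping = variant_io.attach_populations(table, cfg.popmap())
        snp = table.subset_sites((table.sites["var_class"] == "SNP").to_numpy())
        import pandas as pd
        wins = pd.DataFrame([(w["scaffold"], w["start"], w["end"])
                             for w in truth.windows],
                            columns=["scaffold", "start", "end"])
        pi_d = diversity.window_pi(snp, grouping.indices("domestic"), wins)
        labels = np.array([w["label"] for w in truth.windows])
        stat, p = mannwhitneyu(pi_d[labels == "sweep"], pi_d[labels == "neutral"],
                               alternative="less")
        assert p < 0.01

    def test_truth_labels_cover_all_windows(self, small_cohort):
        cfg, table, truth = small_cohort
        n_segments = cfg.n_scaffolds * (cfg.scaffold_length // cfg.segment_bp)
        assert len(truth.windows) == n_segments


class TestDiagnosticInjection:
    def test_injected_loci_recovered(self, tmp_path):
        from anaspop import sweep_scan
        base = cs.SimulationConfig(seed=31, n_scaffolds=2, scaffold_length=30_000)
        spec = cs.DiagnosticSpec("scaffold_1", list(range(1000, 16_000, 1000)),
                                 group="white")
        cfg = cs.inject_diagnostic_locus(base, spec)
        table, truth = cs.simulate_cohort(cfg)
        grouping = variant_io.attach_populations(table, cfg.popmap())
        hits = sweep_scan.diagnostic_variants(
            table, grouping.indices("white"), grouping.indices("non_white"),
            min_called=1)
        found = {(h.scaffold, h.pos) for h in hits}
        injected = {(d["scaffold"], d["pos"]) for d in truth.diagnostics}
        assert injected <= found  # recall 1.0
        assert len(injected) == 15

    def test_collision_shifts_position(self, caplog):
        base = cs.SimulationConfig(seed=32, n_scaffolds=1, scaffold_length=20_000)
        t0, _ = cs.simulate_cohort(base)
        pos = int(t0.sites.pos.iloc[0])
        cfg = cs.inject_diagnostic_locus(
            base, cs.DiagnosticSpec("scaffold_1", [pos]))
        table, truth = cs.simulate_cohort(cfg)
        assert truth.diagnostics[0]["pos"] != pos

    def test_neutral_background_yields_no_diagnostic_hits(self, small_cohort,
                                                          small_grouping):
        from anaspop import sweep_scan
        _, table, _ = small_cohort
        hits = sweep_scan.diagnostic_variants(
            table, small_grouping.indices("white"),
            small_grouping.indices("non_white"), min_called=10)
        # 24 vs 54 chromosomes fixed-opposite by drift: essentially impossible
        assert len(hits) == 0

    def test_truth_json_round_trip(self, tmp_path, small_cohort):
        _, _, truth = small_cohort
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = cs.TruthRecord.from_json(path)
        assert back.window_labels() == truth.window_labels()
        assert back.params["seed"] == truth.params["seed"]


class TestNeutralSfsShape:
    def test_folded_sfs_proportional_to_harmonic_expectation(self):
        # constant-size population, n haplotypes: xi_i ~ 1/i
        n = 8
        arr = cs.branch_sfs(one_pop(), {"p": n}, 60_000, seed=13)
        expected = np.array([0] + [2.0 / i for i in range(1, n)] + [0])
        assert np.allclose(arr[1:n], expected[1:n], rtol=0.05)
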