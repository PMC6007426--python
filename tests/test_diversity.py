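import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from anaspop import diversity
from conftest import make_table
from _oracles import pi_brute_force, wc_site_oracle, windowed_fst_oracle


class TestSiteCounts:
    def test_basic_genotypes(self):
        n, alt, het = diversity.site_allele_counts([0, 1, 2], [0, 1, 2])
        assert (n, alt, het) == (6, 3, 1)

    def test_all_missing(self):
        n, alt, het = diversity.site_allele_counts([-1, -1], [0, 1])
        assert n == 0

    @given(st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_enumeration(self, codes):
        n, alt, het = diversity.site_allele_counts(codes, range(len(codes)))
        called = [c for c in codes if c >= 0]
        assert n == 2 * len(called)
        assert alt == sum(called)
        assert het == sum(1 for c in called if c == 1)


class TestPiSite:
    def test_direct_formula(self):
        assert diversity.pi_site(4, 2) == pytest.approx(2 * 2 * 2 / (4 * 3))

    @pytest.mark.parametrize("j", [0, 4])
    def test_monomorphic_zero(self, j):
        assert diversity.pi_site(4, j) == 0.0

    def test_undefined_below_two(self):
        assert np.isnan(diversity.pi_site(1, 0))

    def test_equals_mean_pairwise_hamming_exhaustively(self):
        for n in range(2, 13):
            for j in range(n + 1):
                assert diversity.pi_site(n, j) == pytest.approx(
                    pi_brute_force(n, j), abs=1e-12), (n, j)


class TestWeirCockerham:
    def test_fixed_difference_hand_values(self):
        a, b, c = diversity.wc_components([4, 4], [1.0, 0.0], [0.0, 0.0])
        assert float(a) == pytest.approx(0.5)
        assert float(b) == pytest.approx(0.0)
        assert float(c) == pytest.approx(0.0)

    def test_identical_populations_nonpositive_a(self):
        a, _, _ = diversity.wc_components([6, 6], [0.3, 0.3], [0.4, 0.4])
        assert float(a) <= 0.0

    def test_random_sites_match_scalar_transliteration(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            g1 = rng.integers(0, 3, rng.integers(2, 8)).tolist()
            g2 = rng.integers(0, 3, rng.integers(2, 8)).tolist()
            oracle = wc_site_oracle([g1, g2])
            n1, n2 = len(g1), len(g2)
            a, b, c = diversity.wc_components(
                [n1, n2],
                [sum(g1) / (2 * n1), sum(g2) / (2 * n2)],
                [g1.count(1) / n1, g2.count(1) / n2])
            assert float(a) == pytest.approx(oracle[0], abs=1e-12)
            assert float(b) == pytest.approx(oracle[1], abs=1e-12)
            assert float(c) == pytest.approx(oracle[2], abs=1e-12)


class TestWindowedStats:
    def test_fixed_differences_give_theta_one(self):
        gt = np.array([[0, 0, 2, 2]] * 5, dtype=np.int8)
        t = make_table(gt)
        wins = pd.DataFrame({"scaffold": ["scaf1"], "start": [0], "end": [1000]})
        theta, n = diversity.window_fst(t, [0, 1], [2, 3], wins)
        assert theta[0] == pytest.approx(1.0)
        assert n[0] == 5

    def test_identical_frequencies_nonpositive(self):
        gt = np.array([[0, 2, 0, 2]] * 4, dtype=np.int8)
        t = make_table(gt)
        wins = pd.DataFrame({"scaffold": ["scaf1"], "start": [0], "end": [1000]})
        theta, _ = diversity.window_fst(t, [0, 1], [2, 3], wins)
        assert theta[0] <= 0.0

    def test_site_order_invariance_and_oracle(self):
        rng = np.random.default_rng(17)
        gt = rng.choice([-1, 0, 1, 2], size=(120, 8),
                        p=[0.05, 0.45, 0.3, 0.2]).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 5000), 120, replace=False))
        t = make_table(gt, positions=pos)
        wins = pd.DataFrame({"scaffold": ["scaf1"], "start": [0], "end": [5000]})
        idx_a, idx_b = [0, 1, 2, 3], [4, 5, 6, 7]
        theta, _ = diversity.window_fst(t, idx_a, idx_b, wins)
        perm = rng.permutation(120)
        theta_p, _ = diversity.window_fst(t.subset_sites(perm).sort(), idx_a, idx_b, wins)
        assert theta[0] == pytest.approx(theta_p[0], abs=1e-12)
        assert theta[0] == pytest.approx(windowed_fst_oracle(gt, idx_a, idx_b), abs=1e-10)
        assert diversity.global_fst(t, idx_a, idx_b) == pytest.approx(theta[0], abs=1e-12)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # regression pin for the estimator form
        gt = np.array([[0, 0, 2, 2], [0, 1, 0, 1], [1, 1, 1, 1]], dtype=np.int8)
        t = make_table(gt)
        wins = pd.DataFrame({"scaffold": ["scaf1"], "start": [0], "end": [1000]})
        theta, _ = diversity.window_fst(t, [0, 1], [2, 3], wins)
        per_site = []
        for row in gt:
            a, b, c = wc_site_oracle([[row[0], row[1]], [row[2], row[3]]])
            per_site.append(a / (a + b + c))
        assert theta[0] != pytest.approx(np.mean(per_site), abs=1e-6)
        assert theta[0] == pytest.approx(windowed_fst_oracle(gt, [0, 1], [2, 3]))

    def test_window_pi_single_site(self):
        gt = np.array([[0, 1, 2]], dtype=np.int8)  # n=6, j=3
        t = make_table(gt, positions=[500], scaffold_length=10_000)
        wins = pd.DataFrame({"scaffold": ["scaf1"], "start": [0], "end": [10_000]})
        pi = diversity.window_pi(t, [0, 1, 2], wins)
        assert pi[0] == pytest.approx(0.6 / 10_000)

    def test_window_pi_empty_window_zero(self):
        t = make_table(np.array([[0, 1]], np.int8), positions=[50])
        wins = pd.DataFrame({"scaffold": ["scaf1"], "start": [100], "end": [200]})
        assert diversity.window_pi(t, [0, 1], wins)[0] == 0.0


class TestMakeWindows:
    def test_arithmetic_example(self):
        w = diversity.make_windows({"s": 25_000})
        assert list(w.start) == [0, 5_000, 10_000, 15_000]
        assert (w.end - w.start == 10_000).all()

    def test_strictly_longer_than_min(self):
        assert len(diversity.make_windows({"s": 10_000})) == 0

    @given(st.integers(1, 100_000))
    @settings(max_examples=50, deadline=None)
    def test_count_matches_closed_form(self, length):
        w = diversity.make_windows({"s": length})
        if length <= 10_000:
            assert len(w) == 0
        else:
            assert len(w) == (length - 10_000) // 5_000 + 1

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            diversity.make_windows({"s": 0})


class TestZScore:
    def test_three_values(self):
        z, mu, sigma = diversity.zscore([0.1, 0.2, 0.3])
        assert list(np.round(z, 10)) == [-1.0, 0.0, 1.0]
        assert (mu, sigma) == (pytest.approx(0.2), pytest.approx(0.1))

    def test_published_standardization_constants(self):
        # F_ST = 0.69 under the genome-wide mu/sigma used in the study
        assert (0.69 - 0.1154) / 0.0678 == pytest.approx(8.4749, abs=1e-4)

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        z1, _, _ = diversity.zscore(x)
        z2, _, _ = diversity.zscore(z1)
        assert np.allclose(z1, z2, atol=1e-12)

    def test_zero_sigma_raises(self):
        with pytest.raises(ValueError):
            diversity.zscore([1.0, 1.0, 1.0])


class TestHetStats:
    def test_counts(self):
        gt = np.array([[0, 1], [0, 1], [0, 1], [0, 2]], dtype=np.int8)
        df = diversity.sample_het_stats(make_table(gt))
        assert df.loc[0, "n_snp_genotypes"] == 0
        assert df.loc[1, "n_het"] == 3
        assert df.loc[1, "het_hom_ratio"] == pytest.approx(3.0)

    def test_bottlenecked_population_more_homozygous(self, small_cohort, small_grouping):
        _, table, _ = small_cohort
        df = diversity.sample_het_stats(table, small_grouping)
        ratios = df.groupby("population")["het_hom_ratio"].mean()
        wild = ratios[["MDN", "MDZ"]].mean()
        dom = ratios[["PK", "CV", "ML", "JD", "SM", "SX", "GY"]].mean()
        assert dom < wild


def test_equilibrium_fst_decreases_with_migration():
    """Two-deme island model: windowed Weir-Cockerham F_ST falls
    monotonically as symmetric migration increases (rank correlation < 0)."""
    import random
    from scipy.stats import spearmanr
    from anaspop import coalescent_sim as cs
    from anaspop.demography import DemographicModel, Split

    def island(M):
        return DemographicModel(
            sampled=("p", "q"), initial_sizes={"p": 1.0, "q": 1.0},
            events=(Split(40.0, "p", "anc", 1.0), Split(40.0, "q", "anc")),
            migration={("p", "q"): M, ("q", "p"): M})

    grid = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
    fsts = []
    rng = random.Random(77)
    for M in grid:
        gts = []
        for _ in range(150):
            g = cs.simulate_genealogy(island(M), {"p": 8, "q": 8}, rng)
            for _, mask in cs.drop_mutations(g, 0.05, 100, rng):
                bits = [(mask >> h) & 1 for h in range(16)]
                codes = [bits[2 * s] + bits[2 * s + 1] for s in range(8)]
                gts.append(codes)
        gt = np.array(gts, dtype=np.int8)
        t = make_table(gt, positions=np.arange(1, len(gt) + 1) * 10)
        fsts.append(diversity.global_fst(t, [0, 1, 2, 3], [4, 5, 6, 7]))
    rho, _ = spearmanr(grid, fsts)
    assert rho < 0
    assert fsts[0] > fsts[-1]
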