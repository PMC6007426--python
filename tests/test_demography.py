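import math

import numpy as np
import pytest

from anaspop import demography as dm
from anaspop import sfs as sfs_mod
from anaspop.demography import (
    DUCK_MODEL2_REAL, FitResult, build_model, compare_aic, composite_loglik,
    duck_model2, expected_sfs, fit, real_to_scaled, scaled_to_real, to_real_units,
)
from anaspop.sfs import FoldedSFS

N_REF = 100_000.0
TRUTH = real_to_scaled(DUCK_MODEL2_REAL, N_REF)


class TestBuildModel:
    def test_model2_event_order_and_times(self):
        model = build_model("model2", TRUTH)
        cd = model.compile()
        kinds = [(e[0], round(e[1], 6)) for e in cd.events]
        t_breed = round(2126 / (2 * N_REF), 6)
        t_dom = round(2228 / (2 * N_REF), 6)
        t_anc = round(249_944 / (2 * N_REF), 6)
        assert kinds == [("merge", t_breed), ("merge", t_breed),
                         ("merge", t_dom), ("merge", t_dom),
                         ("size", t_anc)]
        # bottleneck size attached to the first (breed) merge
        assert cd.events[0][4] == pytest.approx(320 / N_REF)

    def test_model1_is_trifurcation_with_fewer_parameters(self):
        params = {k: v for k, v in TRUTH.items()
                  if k in dm.SCENARIO_PARAMS["model1"]}
        model = build_model("model1", params)
        merges = [e for e in model.compile().events if e[0] == "merge"]
        assert len(merges) == 3
        assert len({e[1] for e in merges}) == 1
        assert dm.SCENARIO_K["model1"] == dm.SCENARIO_K["model2"] - 2

    def test_model3_ordering_guard(self):
        params = {k: v for k, v in TRUTH.items() if not k.startswith(("T_", "nu_dom"))}
        params.update({"nu_anc": TRUTH["nu_anc"], "T_anc": TRUTH["T_anc"],
                       "T_meat": 0.01, "T_egg": 0.02})
        with pytest.raises(ValueError, match="T_meat > T_egg"):
            build_model("model3", params)

    def test_model2_inconsistent_times_rejected(self):
        bad = dict(TRUTH)
        bad["T_breed"] = bad["T_dom"] * 1.5
        with pytest.raises(ValueError, match="T_dom > T_breed"):
            build_model("model2", bad)

    def test_missing_parameter_named(self):
        with pytest.raises(ValueError, match="nu_wild"):
            build_model("model2", {k: v for k, v in TRUTH.items() if k != "nu_wild"})


class TestUnitScaling:
    def test_round_trip_identity(self):
        back = scaled_to_real(real_to_scaled(DUCK_MODEL2_REAL, N_REF), N_REF)
        for k, v in DUCK_MODEL2_REAL.items():
            assert back[k] == pytest.approx(v, rel=1e-12)

    def test_theta_scaling_algebra(self):
        out = to_real_units({"nu_wild": 1.0, "T_dom": 0.0, "m_wild_meat": 0.0},
                            theta=4000.0, L=1e9)
        assert out["n_ref"] == pytest.approx(4000 / (4 * 1.191e-9 * 1e9))
        assert out["n_ref"] == pytest.approx(839.63, abs=0.01)
        assert out["t_dom"] == 0.0

    def test_migration_convention_pinned(self):
        # 3.92 migrants/gen into wild at nu_wild = 0.88842 -> M = 8.8247
        scaled = real_to_scaled(DUCK_MODEL2_REAL, N_REF)
        assert scaled["m_wild_eggdp"] == pytest.approx(2 * 3.92 / 0.88842, rel=1e-12)
        real = scaled_to_real(scaled, N_REF)
        assert real["mig_wild_eggdp"] == pytest.approx(3.92, rel=1e-12)


class TestExpectedSfs:
    def test_single_population_standard_neutral_proportions(self):
        model = dm.DemographicModel(sampled=("p",), initial_sizes={"p": 1.0})
        f = expected_sfs(model, {"p": 4}, 30_000, seed=5)
        assert f.mass[1] == pytest.approx(8 / 11, abs=0.01)
        assert f.mass[2] == pytest.approx(3 / 11, abs=0.01)
        assert f.mass[~f.mask].sum() == pytest.approx(1.0)

    def test_vanishing_split_time_equals_pooled_panmixis(self):
        split = dm.DemographicModel(
            sampled=("p", "q"), initial_sizes={"p": 1.0, "q": 1.0},
            events=(dm.Split(1e-9, "p", "anc", 1.0), dm.Split(1e-9, "q", "anc")))
        f2 = expected_sfs(split, {"p": 3, "q": 3}, 30_000, seed=6)
        pooled = dm.DemographicModel(sampled=("p",), initial_sizes={"p": 1.0})
        f1 = expected_sfs(pooled, {"p": 6}, 30_000, seed=7)
        # marginalize the joint over the pooled count
        pooled_mass = np.zeros(7)
        for i in range(4):
            for j in range(4):
                pooled_mass[i + j] += f2.mass[i, j]
        assert np.allclose(pooled_mass[1:4], f1.mass[1:4], atol=0.015)


class TestCompositeLoglik:
    def _single_cell(self, obs, model):
        mask = np.array([True, False])
        return composite_loglik(
            FoldedSFS(np.array([0.0, obs]), mask),
            FoldedSFS(np.array([0.0, model]), mask))

    def test_hand_arithmetic_single_cell(self):
        # obs = model = 2: 2 ln 2 - 2 - ln 2! = ln 2 - 2
        assert self._single_cell(2.0, 2.0) == pytest.approx(math.log(2) - 2)

    def test_scale_is_profiled_out(self):
        assert self._single_cell(2.0, 17.0) == pytest.approx(math.log(2) - 2)

    def test_self_maximization(self):
        rng = np.random.default_rng(0)
        mask = np.zeros(8, bool)
        mask[0] = True
        obs = FoldedSFS(np.append(0, rng.integers(1, 60, 7)).astype(float), mask)
        best = composite_loglik(obs, obs)
        for _ in range(30):
            other = FoldedSFS(np.append(0, rng.random(7)), mask)
            assert composite_loglik(obs, other) <= best + 1e-9

    def test_masked_cells_ignored(self):
        mask = np.array([True, False])
        a = composite_loglik(FoldedSFS(np.array([0.0, 3.0]), mask),
                             FoldedSFS(np.array([0.0, 1.0]), mask))
        b = composite_loglik(FoldedSFS(np.array([99.0, 3.0]), mask),
                             FoldedSFS(np.array([55.0, 1.0]), mask))
        assert a == b

    def test_dim_mismatch_rejected(self):
        mask = np.array([True, False])
        with pytest.raises(ValueError):
            composite_loglik(FoldedSFS(np.zeros(2), mask),
                             FoldedSFS(np.zeros(3), np.zeros(3, bool)))


class TestFit:
    @pytest.fixture(scope="class")
    def observed_at_truth(self):
        ss = {"wild": 8, "meat": 8, "eggdp": 8}
        p = expected_sfs(build_model("model2", TRUTH), ss, 25_000, seed=3)
        counts = FoldedSFS(np.where(p.mask, 0.0, p.mass * 100_000), p.mask,
                           p.pop_names)
        return ss, counts

    def test_one_parameter_recovery_near_truth(self, observed_at_truth):
        ss, obs = observed_at_truth
        res = fit("model2", TRUTH, obs, ["T_dom"],
                  {"T_dom": (TRUTH["T_dom"] / 3, min(TRUTH["T_dom"] * 3,
                                                     TRUTH["T_anc"] * 0.9))},
                  ss, seed=1, restarts=2, n_reps=3000, maxiter=40)
        assert res.params["T_dom"] == pytest.approx(TRUTH["T_dom"], rel=0.10)
        assert res.aic == pytest.approx(2 * 1 - 2 * res.loglik)

    def test_bounds_excluding_truth_pin_at_boundary(self, observed_at_truth):
        ss, obs = observed_at_truth
        hi = TRUTH["nu_wild"] * 0.4
        res = fit("model2", TRUTH, obs, ["nu_wild"],
                  {"nu_wild": (TRUTH["nu_wild"] * 0.2, hi)},
                  ss, seed=2, restarts=2, n_reps=1500, maxiter=30)
        assert res.params["nu_wild"] == pytest.approx(hi, rel=0.05)

    def test_invalid_bounds_rejected(self, observed_at_truth):
        ss, obs = observed_at_truth
        with pytest.raises(ValueError):
            fit("model2", TRUTH, obs, ["T_dom"], {"T_dom": (0.0, np.inf)}, ss, seed=1)


class TestCompareAic:
    def _fit(self, model, loglik, k):
        return FitResult(model=model, params={}, free_params=tuple(range(k)),
                         loglik=loglik, aic=2 * k - 2 * loglik, converged=True,
                         n_evaluations=0)

    def test_arithmetic(self):
        ranked = compare_aic([self._fit("a", -100.0, 5), self._fit("b", -120.0, 2)])
        assert ranked[0][0].model == "a"
        assert ranked[0][0].aic == 210.0
        assert ranked[1][1] == pytest.approx(244 - 210)

    def test_parsimony_breaks_equal_likelihood(self):
        ranked = compare_aic([self._fit("k5", -100.0, 5), self._fit("k4", -100.0, 4)])
        assert ranked[0][0].model == "k4"

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            compare_aic([self._fit("a", -1.0, 1)])


class TestBootstrap:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        from anaspop import coalescent_sim as cs
        from anaspop.variant_io import attach_populations
        cfg = cs.SimulationConfig(seed=9, n_scaffolds=4, scaffold_length=20_000)
        table, _ = cs.simulate_cohort(cfg)
        grouping = attach_populations(table, cfg.popmap())
        pops = {"wild": grouping.indices("wild"),
                "meat": grouping.indices("meat"),
                "eggdp": grouping.indices("egg")}
        proj = {"wild": 8, "meat": 8, "eggdp": 8}
        ss = {"wild": 8, "meat": 8, "eggdp": 8}
        return table, pops, proj, ss

    def test_same_seed_identical_intervals(self, tiny_setup):
        table, pops, proj, ss = tiny_setup
        kwargs = dict(
            scenario="model2", base_params=TRUTH, free_params=["nu_wild"],
            bounds={"nu_wild": (TRUTH["nu_wild"] / 4, TRUTH["nu_wild"] * 4)},
            pops=pops, projections=proj, sample_sizes=ss, n_boot=2, seed=4,
            n_reps=200, restarts=1, maxiter=5)
        ci1, est1 = dm.bootstrap_ci(table, **kwargs)
        ci2, est2 = dm.bootstrap_ci(table, **kwargs)
        assert ci1 == ci2
        assert est1 == est2

    def test_single_scaffold_degenerate_warns(self, tiny_setup, caplog):
        import logging
        table, pops, proj, ss = tiny_setup
        one = table.subset_sites(
            (table.sites["scaffold"] == "scaffold_1").to_numpy())
        with caplog.at_level(logging.WARNING, logger="anaspop"):
            dm.bootstrap_ci(one, "model2", TRUTH, ["nu_wild"],
                            {"nu_wild": (TRUTH["nu_wild"] / 4, TRUTH["nu_wild"] * 4)},
                            pops, proj, ss, n_boot=2, seed=5, n_reps=100,
                            restarts=1, maxiter=3)
        assert any("scaffold" in r.message for r in caplog.records)
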