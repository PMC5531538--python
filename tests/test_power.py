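import numpy as np
import pytest
from scipy import stats

from stratdiff import (
    ApproachSpec,
    EffectScenario,
    SimulationConfig,
    conditional_type1_oracle,
    min_detectable_beta,
    ncp,
    power_approach,
    power_curves,
    power_filter,
    power_joint,
    power_z,
    simulate_summary,
    z_diff,
)

BALANCED_NULL = EffectScenario(0.0, 0.0, 1, 100_000, 100_000)


class TestNcp:
    def test_no_difference_gives_zero_diff_ncp(self):
        sc = EffectScenario(0.0004, 0.0004, 1, 80_000, 120_000)
        assert ncp("diff", sc) == pytest.approx(0.0)

    def test_balanced_pure_gxs_coincidence(self):
        # with n1 = n2 and R2 = 0 the difference and overall ncps coincide
        sc = EffectScenario(0.00058, 0.0, 0, 100_000, 100_000)
        assert ncp("diff", sc) == pytest.approx(5.385165, abs=1e-5)
        assert ncp("overall", sc) == pytest.approx(ncp("diff", sc), rel=1e-12)

    def test_joint_lambda_scales_with_n(self):
        sc = EffectScenario(0.00058, 0.0, 0, 100_000, 100_000)
        assert ncp("joint", sc) == pytest.approx(58.0, abs=1e-9)
        assert ncp("joint", sc.halved()) == pytest.approx(29.0, abs=1e-9)

    def test_relatedness_increases_diff_ncp(self):
        base = EffectScenario(0.00058, 0.0, 0)
        rel = EffectScenario(0.00058, 0.0, 0, relatedness_r=0.05)
        assert ncp("diff", rel) > ncp("diff", base)

    def test_ncp_matches_z_diff_on_estimates(self):
        # consistency between the scenario algebra and the test statistic:
        # plugging the exact betas and closed-form ses into z_diff
        # reproduces the noncentrality
        maf, n1, n2 = 0.3, 60_000, 140_000
        sg = np.sqrt(2 * maf * (1 - maf))
        b1, b2 = 0.03, -0.01
        sc = EffectScenario((b1 * sg) ** 2, (b2 * sg) ** 2, -1, n1, n2)
        z = z_diff(b1, 1 / (sg * np.sqrt(n1)), b2, 1 / (sg * np.sqrt(n2))).statistic
        assert ncp("diff", sc) == pytest.approx(z, rel=1e-12)


class TestPowerZ:
    def test_size_equals_level_at_zero_ncp(self):
        for alpha in (0.05, 1e-5, 5e-8):
            assert power_z(0.0, alpha) == pytest.approx(alpha, rel=1e-9)

    def test_monotone_in_ncp_and_alpha(self):
        assert power_z(3.0, 0.05) > power_z(2.0, 0.05) > power_z(1.0, 0.05)
        assert power_z(3.0, 0.05) > power_z(3.0, 0.01)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(50)
        ncp_val, alpha, n = 2.5, 0.01, 1_000_000
        z = rng.normal(ncp_val, 1.0, n)
        crit = stats.norm.isf(alpha / 2)
        mc = np.mean(np.abs(z) > crit)
        assert power_z(ncp_val, alpha) == pytest.approx(
            mc, abs=3 * np.sqrt(mc * (1 - mc) / n))


class TestPowerJoint:
    def test_size_equals_level(self):
        assert power_joint(0.0, 1e-5) == pytest.approx(1e-5, rel=1e-9)

    def test_monotone_limit(self):
        assert power_joint(1000.0, 1e-5) > 0.9999

    def test_matches_monte_carlo_two_shifted_normals(self):
        rng = np.random.default_rng(51)
        lam, alpha, n = 29.0, 1e-5, 1_000_000
        mu = np.sqrt(lam / 2)
        c = rng.normal(mu, 1, n) ** 2 + rng.normal(mu, 1, n) ** 2
        mc = np.mean(c > stats.chi2.isf(alpha, 2))
        assert power_joint(lam, alpha) == pytest.approx(
            mc, abs=3 * np.sqrt(mc * (1 - mc) / n))


class TestPowerFilter:
    def test_vacuous_threshold(self):
        assert power_filter("none", BALANCED_NULL, 0.05) == 1.0
        sc = EffectScenario(0.0005, 0.0, 0)
        assert power_filter("overall", sc, 1 - 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_pure_gxs_null_stratum_contributes_size_only(self):
        sc = EffectScenario(0.0005, 0.0, 0)
        p2_alone = power_z(0.0, 0.05 / 2)
        assert p2_alone == pytest.approx(0.025, rel=1e-9)
        p1 = power_z(ncp("strat1", sc), 0.025)
        combined = power_filter("strat", sc, 0.05)
        assert combined == pytest.approx(1 - (1 - p1) * (1 - 0.025), rel=1e-9)

    def test_overall_filter_hand_value(self):
        sc = EffectScenario(0.00058, 0.0, 0, 100_000, 100_000)
        assert power_filter("overall", sc, 1e-5) == pytest.approx(0.8335, abs=5e-4)


class TestPowerApproach:
    def test_no_filter_reduces_to_difference_power(self):
        sc = EffectScenario(0.00058, 0.0, 0)
        res = power_approach(ApproachSpec(filter="none"), sc)
        assert res.power_filter == 1.0
        assert res.power_approach == pytest.approx(power_z(ncp("diff", sc), 5e-8))

    def test_two_stage_scales_ncp_by_sqrt_half(self):
        sc = EffectScenario(0.00058, 0.0, 0)
        res = power_approach(
            ApproachSpec(filter="joint", layout="two_stage"), sc, M=10)
        assert res.ncp_diff == pytest.approx(ncp("diff", sc) / np.sqrt(2), rel=1e-12)

    def test_m_one_uses_nominal_level(self):
        sc = EffectScenario(0.00058, 0.0, 0)
        res = power_approach(ApproachSpec(filter="overall"), sc, M=1)
        assert res.power_diff == pytest.approx(power_z(ncp("diff", sc), 0.05))

    def test_one_stage_dependent_filter_flagged_approximate(self):
        sc = EffectScenario(0.00058, 0.0, 0)
        assert power_approach(ApproachSpec(filter="joint"), sc, M=5).approximate
        assert not power_approach(ApproachSpec(filter="overall"), sc, M=5).approximate

    def test_product_structure(self):
        sc = EffectScenario(0.00058, 0.0, 0)
        res = power_approach(ApproachSpec(filter="overall"), sc, M=100)
        assert res.power_approach == pytest.approx(
            res.power_filter * res.power_diff, rel=1e-12)


class TestMinDetectableBeta:
    @pytest.mark.parametrize("n,maf,expected", [
        (200_000, 0.05, 0.029),
        (200_000, 0.30, 0.014),
        (100_000, 0.05, 0.041),
        (100_000, 0.30, 0.019),
    ])
    def test_reference_designs(self, n, maf, expected):
        assert round(min_detectable_beta(n, maf), 3) == expected

    def test_round_trip_through_power(self):
        beta = min_detectable_beta(150_000, 0.2, alpha=0.05, target_power=0.8)
        sg = np.sqrt(2 * 0.2 * 0.8)
        # exact up to the far-tail term power_z keeps (~1e-6 at these ncps)
        assert power_z(beta * sg * np.sqrt(150_000 / 2), 0.05) == pytest.approx(
            0.8, abs=1e-5)

    def test_quadrupling_n_halves_beta(self):
        assert min_detectable_beta(400_000, 0.1) == pytest.approx(
            min_detectable_beta(100_000, 0.1) / 2, rel=1e-12)


class TestConditionalType1Oracle:
    def test_overall_filter_is_exactly_nominal(self):
        val = conditional_type1_oracle("overall", 0.05, BALANCED_NULL)
        assert val == pytest.approx(0.05, abs=1e-4)

    def test_joint_and_strat_filters_inflate(self):
        joint = conditional_type1_oracle("joint", 0.05, BALANCED_NULL)
        strat = conditional_type1_oracle("strat", 0.05, BALANCED_NULL)
        assert joint == pytest.approx(0.498, abs=2e-3)
        assert strat == pytest.approx(0.426, abs=2e-3)

    def test_oracle_matches_simulation(self):
        spec = ApproachSpec(filter="joint", alpha_filter=0.05)
        from stratdiff import estimate_type1
        res = estimate_type1(SimulationConfig(n_variants=400_000, seed=60), spec)
        oracle = conditional_type1_oracle("joint", 0.05, BALANCED_NULL)
        se3 = 3 * np.sqrt(oracle * (1 - oracle) / res.n_tested)
        assert res.rate == pytest.approx(oracle, abs=se3)

    def test_non_null_scenario_rejected(self):
        with pytest.raises(ValueError):
            conditional_type1_oracle("joint", 0.05, EffectScenario(0.001, 0.0, 0))


class TestPowerSimulationAgreement:
    def test_alternative_scenario_rejection_rate(self):
        """Analytical difference-test power matches the simulated rejection
        rate under a genuine GxS alternative."""
        maf, n1, n2 = 0.05, 100_000, 100_000
        sg = np.sqrt(2 * maf * (1 - maf))
        beta1, beta2 = 0.03, 0.01
        cfg = SimulationConfig(n_variants=100_000, maf=maf, beta1=beta1,
                               beta2=beta2, n1=n1, n2=n2, seed=61)
        sim = simulate_summary(cfg)
        p = z_diff(sim.beta1, sim.se1, sim.beta2, sim.se2).p_value
        alpha = 1e-3
        rate = np.mean(p < alpha)
        sc = EffectScenario((beta1 * sg) ** 2, (beta2 * sg) ** 2, 1, n1, n2)
        analytical = power_z(ncp("diff", sc), alpha)
        se3 = 3 * np.sqrt(analytical * (1 - analytical) / cfg.n_variants)
        # the simulator's se carries the small (1 - R^2) factor the scenario
        # algebra drops; at these effect sizes the discrepancy is << MC error
        assert rate == pytest.approx(analytical, abs=se3)


class TestPowerCurves:
    def test_f_symmetry_of_unfiltered_difference_power(self):
        """Unfiltered difference-test power is symmetric in f <-> 1/f when
        the absolute effect pattern is mirrored."""
        n = 200_000
        for f in (0.25, 0.5, 3.0):
            n1 = int(n / (1 + f))
            sc_a = EffectScenario(0.00014, 0.00014, -1, n1, n - n1)
            sc_b = EffectScenario(0.00014, 0.00014, -1, n - n1, n1)
            pa = power_z(ncp("diff", sc_a), 5e-8)
            pb = power_z(ncp("diff", sc_b), 5e-8)
            assert pa == pytest.approx(pb, rel=1e-12)

    def test_balanced_design_maximizes_difference_power(self):
        n = 200_000
        powers = []
        for n1 in (40_000, 70_000, 100_000, 130_000, 160_000):
            sc = EffectScenario(0.00058, 0.0, 0, n1, n - n1)
            powers.append(power_z(ncp("diff", sc), 5e-8))
        assert max(powers) == powers[2]

    def test_long_format_table(self):
        scenarios = [EffectScenario(0.00058, 0.0, 0),
                     EffectScenario(0.00014, 0.00014, -1)]
        specs = [ApproachSpec(filter="none"), ApproachSpec(filter="overall")]
        df = power_curves(scenarios, specs, M=10)
        assert len(df) == 4
        assert set(df["filter"]) == {"none", "overall"}
        assert ((df["power_approach"] >= 0) & (df["power_approach"] <= 1)).all()

    def test_alpha_filter_grid_endpoints(self):
        sc = EffectScenario(0.00058, 0.0, 0)
        specs = [ApproachSpec(filter="overall", alpha_filter=a)
                 for a in (0.05, 1e-5, 5e-8)]
        df = power_curves([sc], specs, M=10)
        # filter power decreases as the threshold tightens
        pf = df.sort_values("alpha_filter", ascending=False)["power_filter"]
        assert pf.is_monotonic_decreasing
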