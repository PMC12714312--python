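import numpy as np
import pytest

from prostox_cea import (
    calibrate_distribution, ceac, classify_quadrant, default_psa_specs,
    run_dsa, run_psa, compare_arms,
)
from prostox_cea.sensitivity import BETA, FIXED, GAMMA, DistributionSpec
import pandas as pd

from prostox_cea.sensitivity import PsaResult


@pytest.fixture(scope="module")
def small_dsa(params, life_table):
    return run_dsa(params, life_table=life_table)


class TestDsa:
    def test_zero_delta_reproduces_base_case(self, params, life_table):
        res = run_dsa(params, delta=0.0, life_table=life_table)
        np.testing.assert_allclose(res.table["low"], res.base_outcome)
        np.testing.assert_allclose(res.table["high"], res.base_outcome)

    def test_test_cost_range_is_exactly_affine(self, small_dsa):
        row = small_dsa.table.set_index("parameter").loc["c_test"]
        # savings have slope -1 in the test price, so +/-20% of $4000 spans $1600
        assert row["range"] == pytest.approx(1600.0, abs=1e-6)
        assert abs(row["low"] - small_dsa.base_outcome) == pytest.approx(
            abs(row["high"] - small_dsa.base_outcome))

    def test_soc_surgery_utilization_tops_the_tornado(self, small_dsa):
        assert small_dsa.top_parameter() == "soc_prostatectomy_utilization"

    def test_surgery_cost_is_second(self, small_dsa):
        assert small_dsa.table.iloc[1]["parameter"] == "c_prostatectomy"

    def test_outcomes_bracket_base_for_monotone_parameters(self, small_dsa):
        for _, row in small_dsa.table.iterrows():
            lo, hi = min(row["low"], row["high"]), max(row["low"], row["high"])
            assert lo - 1e-9 <= small_dsa.base_outcome <= hi + 1e-9


class TestDistributionCalibration:
    def test_gamma_moment_matching(self):
        dist = calibrate_distribution(DistributionSpec("c", GAMMA, 100.0, 10.0))
        assert dist.kwds["a"] == pytest.approx(100.0)
        assert dist.kwds["scale"] == pytest.approx(1.0)
        assert dist.mean() == pytest.approx(100.0)
        assert dist.std() == pytest.approx(10.0)

    def test_beta_moment_matching(self):
        dist = calibrate_distribution(DistributionSpec("u", BETA, 0.9, 0.05))
        assert dist.kwds["a"] == pytest.approx(31.5)
        assert dist.kwds["b"] == pytest.approx(3.5)
        assert dist.mean() == pytest.approx(0.9)
        assert dist.std() == pytest.approx(0.05)

    def test_fixed_is_point_mass(self):
        dist = calibrate_distribution(DistributionSpec("x", FIXED, 0.5, 0.0))
        assert np.all(dist.rvs(10) == 0.5)

    def test_infeasible_beta_names_parameter(self):
        with pytest.raises(ValueError, match="p_bad"):
            calibrate_distribution(DistributionSpec("p_bad", BETA, 0.99, 0.2))

    @pytest.mark.parametrize("spec", [
        DistributionSpec("cost", GAMMA, 2914.90, 291.49),
        DistributionSpec("prob", BETA, 0.1189, 0.01189),
        DistributionSpec("util", BETA, 0.70, 0.07),
    ])
    def test_empirical_moments_match_within_mc_error(self, spec):
        rng = np.random.default_rng(123)
        draws = calibrate_distribution(spec).rvs(size=100_000, random_state=rng)
        n = draws.size
        se_mean = spec.se / np.sqrt(n)
        assert draws.mean() == pytest.approx(spec.mean, abs=2 * se_mean)
        # SE of the sample SD is about se / sqrt(2n) for near-normal shapes;
        # allow a generous factor for skew
        assert draws.std() == pytest.approx(spec.se, rel=0.02)

    def test_default_specs_cover_families(self, params):
        specs = {s.name: s for s in default_psa_specs(params)}
        assert specs["c_prostatectomy"].family == GAMMA
        assert specs["u_notox"].family == BETA
        assert specs["tox_p1_cfrt"].family == BETA
        assert specs["radiation_adherence"].family == FIXED  # mean 1: no feasible beta
        assert specs["d_cost"].family == FIXED
        for s in specs.values():
            if s.family != FIXED:
                assert s.se == pytest.approx(0.10 * s.mean)


class TestQuadrants:
    @pytest.mark.parametrize("dc, de, expected", [
        (-1.0, 0.1, "SE"), (1.0, -0.1, "NW"), (1.0, 0.1, "NE"), (-1.0, -0.1, "SW"),
        (0.0, 0.0, "SE"), (0.0, 0.1, "SE"), (1.0, 0.0, "NW"),
    ])
    def test_classification(self, dc, de, expected):
        assert classify_quadrant(dc, de) == expected


class TestPsa:
    def test_all_fixed_specs_reproduce_base_case(self, params, life_table):
        specs = [DistributionSpec(s.name, FIXED, s.mean, 0.0)
                 for s in default_psa_specs(params)]
        res = run_psa(params, specs=specs, n=5, seed=0, life_table=life_table)
        base = compare_arms(params, life_table).cea
        np.testing.assert_allclose(res.frame["delta_cost"], base.delta_cost, rtol=1e-12)
        np.testing.assert_allclose(res.frame["delta_qaly"], base.delta_qalys, rtol=1e-12)

    def test_seed_reproducibility_is_bit_identical(self, params, life_table):
        a = run_psa(params, n=50, seed=42, life_table=life_table)
        b = run_psa(params, n=50, seed=42, life_table=life_table)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_different_seeds_differ(self, params, life_table):
        a = run_psa(params, n=20, seed=1, life_table=life_table)
        b = run_psa(params, n=20, seed=2, life_table=life_table)
        assert not np.allclose(a.frame["delta_cost"], b.frame["delta_cost"])

    def test_most_iterations_are_dominant(self, params, life_table):
        res = run_psa(params, n=400, seed=9, life_table=life_table)
        assert res.quadrant_fractions()["SE"] > 0.85
        assert (res.frame["delta_cost"] < 0).all()


class TestCeac:
    @staticmethod
    def psa_from(dc, de):
        frame = pd.DataFrame({
            "iteration": range(len(dc)), "delta_cost": dc, "delta_qaly": de,
            "quadrant": [classify_quadrant(c, e) for c, e in zip(dc, de)]})
        return PsaResult(n=len(dc), seed=0, frame=frame)

    def test_all_dominant_gives_probability_one(self):
        psa = self.psa_from([-100.0, -50.0], [0.1, 0.2])
        curve = ceac(psa, [0, 50_000, 100_000])
        np.testing.assert_array_equal(curve.probability, 1.0)

    def test_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(4)
        psa = self.psa_from(rng.normal(0, 5000, 500), rng.uniform(0.01, 0.3, 500))
        curve = ceac(psa, np.arange(0, 150_001, 10_000))
        assert np.all(np.diff(curve.probability) >= 0)

    def test_degenerate_dominant_base_case_is_step_at_one(self, params, life_table):
        specs = [DistributionSpec(s.name, FIXED, s.mean, 0.0)
                 for s in default_psa_specs(params)]
        res = run_psa(params, specs=specs, n=3, seed=0, life_table=life_table)
        curve = ceac(res, [0, 100_000])
        np.testing.assert_array_equal(curve.probability, 1.0)

    def test_invalid_grid_rejected(self):
        psa = self.psa_from([-1.0], [0.1])
        with pytest.raises(ValueError):
            ceac(psa, [])
        with pytest.raises(ValueError):
            ceac(psa, [100, 50])
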