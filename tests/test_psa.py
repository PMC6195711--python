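"""Distribution fitting and the Monte-Carlo uncertainty analysis."""

import dataclasses

import numpy as np
import pytest

from asthmacea import psa
from asthmacea.cea import run_deterministic_cea


class TestFitDistribution:
    def test_beta_symmetry(self):
        spec = psa.fit_distribution("beta", 0.5, 0.4, 0.6)
        assert spec.params["a"] == pytest.approx(spec.params["b"])

    def test_beta_gamma_mean_matches_value(self):
        for fam, v, lo, hi in [("beta", 0.5583, 0.4435, 0.6731),
                               ("beta", 0.09273, 0.07489, 0.11021),
                               ("gamma", 552.13, 468.03, 636.23),
                               ("gamma", 2.23, 1.91, 2.54)]:
            spec = psa.fit_distribution(fam, v, lo, hi)
            assert spec.mean() == pytest.approx(v, rel=1e-9)

    def test_lognormal_median_matches_value(self):
        spec = psa.fit_distribution("lognormal", 3.059, 1.632, 5.733)
        assert spec.median() == pytest.approx(3.059)

    def test_gamma_monte_carlo_mean(self):
        spec = psa.fit_distribution("gamma", 552.13, 468.03, 636.23)
        rng = np.random.default_rng(1)
        draws = psa.sample_spec(spec, rng, 1_000_000)
        assert draws.mean() == pytest.approx(552.13, rel=0.01)

    def test_lognormal_percentiles_near_ci(self):
        spec = psa.fit_distribution("lognormal", 3.059, 1.632, 5.733)
        rng = np.random.default_rng(2)
        draws = psa.sample_spec(spec, rng, 500_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(1.632, rel=0.05)
        assert hi == pytest.approx(5.733, rel=0.05)

    def test_quantile_method_matches_endpoints(self):
        from scipy import stats
        spec = psa.fit_distribution("beta", 0.3842, 0.2882, 0.4802,
                                    method="quantile")
        d = stats.beta(spec.params["a"], spec.params["b"])
        assert d.ppf(0.025) == pytest.approx(0.2882, abs=1e-3)
        assert d.ppf(0.975) == pytest.approx(0.4802, abs=1e-3)

    def test_dirichlet_mean_exact(self):
        probs = np.array([0.122, 0.152, 0.030, 0.696])
        spec = psa.fit_dirichlet_row(probs, n_eff=16)
        alpha = spec.params["alpha"]
        np.testing.assert_allclose(alpha / alpha.sum(), probs, atol=1e-12)

    def test_degenerate_range_collapses(self):
        spec = psa.fit_distribution("beta", 0.3, 0.3, 0.3)
        assert spec.family == "degenerate"
        rng = np.random.default_rng(0)
        assert np.all(psa.sample_spec(spec, rng, 5) == 0.3)

    @pytest.mark.parametrize("fam,v,lo,hi", [
        ("beta", 1.2, 0.9, 1.4), ("gamma", -1.0, -2.0, 0.5),
        ("lognormal", 0.0, 0.0, 1.0)])
    def test_out_of_support_rejected(self, fam, v, lo, hi):
        with pytest.raises(ValueError):
            psa.fit_distribution(fam, v, lo, hi)


@pytest.fixture(scope="module")
def psa_result(base_params):
    return psa.run_psa(base_params, n_draws=1500, seed=123)


class TestRunPsa:
    def test_seed_determinism(self, base_params):
        a = psa.run_psa(base_params, n_draws=60, seed=42)
        b = psa.run_psa(base_params, n_draws=60, seed=42)
        for arm in ("RMTAC_UC", "UC"):
            assert a.arms[arm].equals(b.arms[arm])
        assert a.summary() == b.summary()

    def test_degenerate_draws_equal_deterministic(self, base_params):
        res = psa.run_psa(base_params, n_draws=5, seed=0, degenerate=True)
        det = run_deterministic_cea(base_params)
        inc = res.incrementals
        assert inc["delta_cost"].std() == 0.0
        assert inc["delta_cost"][0] == pytest.approx(det.delta_cost, abs=1e-9)
        assert inc["delta_qalys"][0] == pytest.approx(det.delta_qalys, abs=1e-12)

    def test_draw_count_and_rejections(self, psa_result):
        assert len(psa_result.arms["UC"]) == 1500
        assert psa_result.n_rejected < 0.01 * 1500

    def test_sampled_parameter_means_converge(self, base_params):
        specs = psa.fit_all(base_params)
        rng = np.random.default_rng(7)
        n = 4000
        draws = psa._sample_draws(specs, rng, n)
        for name, v in (("p_BE", 0.09273), ("c_F", 552.13), ("u_CD", 0.5316)):
            x = draws[name]
            se = x.std() / np.sqrt(n)
            assert abs(x.mean() - v) < 3 * se

    def test_outcomes_physical(self, psa_result):
        for arm, df in psa_result.arms.items():
            assert (df["qalys"] <= df["life_years"]).all()
            assert (df[["qalys", "life_years", "hospitalizations",
                        "total_cost"]] >= 0).all().all()

    def test_base_case_dominant_with_interval_spanning_zero(self, psa_result):
        s = psa_result.summary()
        assert s["incremental"]["delta_cost"]["mean"] < 0
        assert s["incremental"]["delta_qalys"]["mean"] > 0
        lo, hi = s["incremental"]["delta_qalys"]["ci95"]
        assert lo < 0 < hi           # per-draw QALY gain is uncertain in sign

    def test_ceac_endpoints(self, psa_result):
        inc = psa_result.incrementals
        psa_result.ceac_grid = np.array([0.0, 1e12])
        curve = psa_result.ceac()
        assert curve["p_cost_effective"][0] == pytest.approx(
            (inc["delta_cost"] < 0).mean())
        assert curve["p_cost_effective"][1] == pytest.approx(
            (inc["delta_qalys"] > 0).mean(), abs=1e-3)

    def test_dominance_fraction_is_se_quadrant(self, psa_result):
        inc = psa_result.incrementals
        frac = ((inc["delta_cost"] < 0) & (inc["delta_qalys"] > 0)).mean()
        assert psa_result.summary()["dominance_fraction"] == pytest.approx(frac)

    def test_icer_ratio_of_means_consistency(self, psa_result):
        s = psa_result.summary()
        inc = psa_result.incrementals
        expected = inc["delta_cost"].mean() / inc["delta_qalys"].mean()
        assert s["icer_per_qaly"]["ratio_of_means"] == pytest.approx(expected)

    def test_correlated_draws_tied(self, base_params):
        specs = psa.fit_all(base_params)
        rng = np.random.default_rng(3)
        draws = psa._sample_draws(specs, rng, 10)
        ar, au, p_EG, u, c, rmtac, valid = psa._assemble(base_params, draws)
        np.testing.assert_array_equal(u[:, 0], u[:, 1])    # u_A = u_B
        np.testing.assert_array_equal(u[:, 2], u[:, 3])    # u_C = u_D
        # p_EF = p_FE: both arms share the same re-exacerbation draw
        np.testing.assert_array_equal(ar[:, 4, 5], ar[:, 5, 4])
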