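"""Posterior sampling, summaries and convergence diagnostics."""

import numpy as np
import pytest
from scipy import stats

from molcount import (
    PriorSpec,
    SamplerConfig,
    credible_interval,
    fit_joint,
    fit_single,
    gelman_rubin,
    map_estimate,
)
from molcount.inference import grid_posterior_p

from conftest import ks_distance, make_score

FAST = SamplerConfig(n_chains=2, n_draws=4000, n_burnin=1000, seed=0)


class TestSummaries:
    def test_integer_map_is_mode_with_smallest_tie(self):
        assert map_estimate(np.array([3, 3, 3, 5, 5]), integer=True) == 3
        assert map_estimate(np.array([7, 7, 2, 2, 9]), integer=True) == 2

    def test_real_map_tracks_density_peak(self, rng):
        x = rng.beta(40, 60, size=200_000)
        mode = 39 / 98  # (a-1)/(a+b-2)
        assert map_estimate(x) == pytest.approx(mode, abs=0.01)

    def test_credible_interval_matches_analytic_quantiles(self, rng):
        x = rng.beta(40, 60, size=100_000)
        lo, hi = credible_interval(x)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 40, 60), abs=0.01)
        assert hi == pytest.approx(stats.beta.ppf(0.975, 40, 60), abs=0.01)

    def test_credible_interval_ordering_and_level(self, rng):
        x = rng.normal(size=5000)
        lo, hi = credible_interval(x, level=0.5)
        assert lo <= hi
        with pytest.raises(ValueError):
            credible_interval(x, level=1.5)


class TestGelmanRubin:
    def test_identical_chains_near_one(self, rng):
        chain = rng.normal(size=20_000)
        rhat = gelman_rubin(np.stack([chain, chain, chain]))
        # standard PSRF carries a (n-1)/n factor, so "1" only up to O(1/n)
        assert rhat == pytest.approx(1.0, abs=1e-3)
        assert rhat >= 1.0 - 0.01

    def test_well_mixed_independent_chains_near_one(self, rng):
        chains = rng.normal(size=(4, 10_000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self, rng):
        chains = rng.normal(size=(2, 5000)) + np.array([[0.0], [5.0]])
        assert gelman_rubin(chains) > 1.5

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100)))


class TestFitSingle:
    def test_no_positives_forces_p_to_zero(self):
        score = make_score(f_l=0.01, V=2000, V_plus=0)
        res = fit_single(score, n_sat_fixed=205, config=FAST)
        assert res.map["p[0]"] < 0.01
        assert np.quantile(res.draws["p[0]"], 0.95) < 0.02

    def test_all_positive_saturating_design(self):
        # f_l=1, n_sat=1: q = p, all positives drive p toward 1
        score = make_score(f_l=1.0, V=200, V_plus=200)
        res = fit_single(score, n_sat_fixed=1, config=FAST)
        assert res.map["p[0]"] > 0.98

    def test_matches_grid_quadrature_posterior(self):
        score = make_score(f_l=0.01, V=1000, V_plus=450)
        res = fit_single(
            score, n_sat_fixed=205,
            config=SamplerConfig(n_chains=2, n_draws=10_000, n_burnin=2000, seed=4),
        )
        grid, dens = grid_posterior_p(score, 205)
        assert ks_distance(res.draws["p[0]"], grid, dens) < 0.05

    def test_deterministic_given_seed(self):
        score = make_score(f_l=0.01, V=500, V_plus=100)
        r1 = fit_single(score, n_sat_fixed=205, config=FAST)
        r2 = fit_single(score, n_sat_fixed=205, config=FAST)
        assert np.array_equal(r1.draws["p[0]"], r2.draws["p[0]"])
        r3 = fit_single(
            score, n_sat_fixed=205,
            config=SamplerConfig(n_chains=2, n_draws=4000, n_burnin=1000, seed=99),
        )
        assert not np.array_equal(r1.draws["p[0]"], r3.draws["p[0]"])

    def test_rejects_bad_n_sat(self):
        score = make_score(f_l=0.01, V=100, V_plus=10)
        with pytest.raises(ValueError):
            fit_single(score, n_sat_fixed=0)


class TestFitJoint:
    def test_two_samples_fixed_nsat_match_independent_quadrature(self):
        s1 = make_score(f_l=0.01, V=1500, V_plus=500, sample_id="a")
        s2 = make_score(f_l=0.05, V=900, V_plus=700, sample_id="b")
        res = fit_joint(
            [s1, s2], n_sat_fixed=205,
            config=SamplerConfig(n_chains=2, n_draws=10_000, n_burnin=2000, seed=8),
        )
        for j, s in enumerate((s1, s2)):
            grid, dens = grid_posterior_p(s, 205)
            assert ks_distance(res.draws[f"p[{j}]"], grid, dens) < 0.05

    def test_all_zero_positives_is_valid_not_error(self):
        # with n_sat=0 excluded by the prior, zero positives everywhere pull
        # every binding probability toward 0 (p is unidentified at n_sat=0)
        scores = [
            make_score(f_l=0.01, V=500, V_plus=0, sample_id=f"s{j}") for j in range(3)
        ]
        res = fit_joint(scores, priors=PriorSpec(n_sat_lower=1), config=FAST)
        for j in range(3):
            assert res.map[f"p[{j}]"] < 0.05

    def test_draw_shapes_and_summary_consistency(self):
        scores = [
            make_score(f_l=0.01, V=400, V_plus=150, sample_id="a"),
            make_score(f_l=0.02, V=400, V_plus=350, sample_id="b"),
        ]
        res = fit_joint(scores, config=FAST)
        assert set(res.draws) == {"p[0]", "p[1]", "n_sat"}
        for name, arr in res.draws.items():
            assert arr.shape == (2, 4000)
            lo, hi = res.ci[name]
            assert lo <= hi
            assert res.rhat[name] >= 1.0 - 0.01
        assert float(res.draws["n_sat"][0, 0]) == int(res.draws["n_sat"][0, 0])

    def test_continuous_relaxation_agrees_on_nsat_location(self):
        # integer treatment vs real-valued relaxation should land in the
        # same region when the posterior is well identified
        from molcount import generate_study

        scores = generate_study(n_sat=50, V=1500, seed=3)
        cfg_kw = dict(n_chains=2, n_draws=8000, n_burnin=8000, seed=1)
        res_int = fit_joint(scores, config=SamplerConfig(**cfg_kw))
        res_real = fit_joint(
            scores, config=SamplerConfig(continuous_nsat=True, **cfg_kw)
        )
        assert res_int.map["n_sat"] == pytest.approx(res_real.map["n_sat"], rel=0.2)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_joint([])


class TestPriors:
    def test_informative_beta_prior_shifts_small_sample_posterior(self):
        score = make_score(f_l=1.0, V=4, V_plus=2)
        flat = fit_single(score, n_sat_fixed=1, config=FAST)
        skew = fit_single(
            score, n_sat_fixed=1, priors=PriorSpec(p_alpha=20, p_beta=2), config=FAST
        )
        assert np.mean(skew.draws["p[0]"]) > np.mean(flat.draws["p[0]"]) + 0.2

    def test_prior_spec_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(p_alpha=0)
        with pytest.raises(ValueError):
            PriorSpec(n_sat_lower=10, n_sat_upper=5)
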