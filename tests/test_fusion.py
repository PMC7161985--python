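"""Candidate sampling, bin probabilities, vote likelihoods, and MAP
selection, each against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm, spearmanr

from sdmfuse.delta import predict_biomass
from sdmfuse.fusion import (ExpertVotes, FusionConfig, candidate_logprior,
                            candidate_projections, directional_bin_probs,
                            fused_evaluate, multinomial_logpmf,
                            posterior_select, sample_candidates,
                            score_candidates, sensitivity_bin_probs,
                            vote_loglik)


@pytest.fixture(scope="module")
def envs(environment):
    depth = environment.depth.values.ravel()
    sst = environment.seasonal_sst("fall").isel(year=-1).values.ravel()
    base = {"sst": sst, "depth": depth}
    fut = {"sst": sst + 1.2, "depth": depth}
    return base, fut


def _votes(sens, direc):
    return ExpertVotes("x", np.asarray(sens), np.asarray(direc))


class TestSampling:
    def test_zero_covariance_collapses_to_beta(self, fitted_delta, rng):
        import copy

        fit = copy.deepcopy(fitted_delta)
        fit.stage2.cov = np.zeros_like(fit.stage2.cov)
        draws = sample_candidates(fit, 20, rng)
        np.testing.assert_allclose(
            draws, np.tile(fit.stage2.beta, (20, 1)), atol=1e-12)

    def test_moments_recovered(self, fitted_delta, rng):
        draws = sample_candidates(fitted_delta, 1000, rng)
        beta, V = fitted_delta.stage2.beta, fitted_delta.stage2.cov
        se = np.sqrt(np.diag(V) / 1000)
        assert np.all(np.abs(draws.mean(axis=0) - beta) <= 4 * se + 1e-12)
        S = np.cov(draws.T, ddof=1)
        rel = np.linalg.norm(S - V) / np.linalg.norm(V)
        assert rel < 0.2

    def test_seeded_determinism(self, fitted_delta):
        a = sample_candidates(fitted_delta, 50, np.random.default_rng(9))
        b = sample_candidates(fitted_delta, 50, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestCandidateProjections:
    def test_beta_reproduces_delta_gam_prediction(self, fitted_delta, envs):
        base, fut = envs
        b, f = candidate_projections(fitted_delta, fitted_delta.stage2.beta,
                                     base, fut)
        np.testing.assert_allclose(
            b[0], predict_biomass(fitted_delta, base, warn_extrapolation=False),
            rtol=1e-12)
        np.testing.assert_allclose(
            f[0], predict_biomass(fitted_delta, fut, warn_extrapolation=False),
            rtol=1e-12)

    def test_intercept_shift_scales_projection(self, fitted_delta, envs):
        base, fut = envs
        theta = fitted_delta.stage2.beta.copy()
        shifted = theta.copy()
        shifted[0] += 0.7
        b, _ = candidate_projections(fitted_delta, np.vstack([theta, shifted]),
                                     base, fut)
        np.testing.assert_allclose(b[1], b[0] * np.exp(0.7), rtol=1e-10)

    def test_stage1_identical_across_candidates(self, fitted_delta, envs, rng):
        base, fut = envs
        thetas = sample_candidates(fitted_delta, 3, rng)
        b, _ = candidate_projections(fitted_delta, thetas, base, fut)
        from sdmfuse.delta import predict_presence
        p1 = predict_presence(fitted_delta, base, warn_extrapolation=False)
        for i in range(3):
            logb = np.log(b[i] / p1)
            X = fitted_delta.stage2.design_matrix(base, warn_extrapolation=False)
            np.testing.assert_allclose(logb, X @ thetas[i], rtol=1e-8)


class TestBinProbs:
    def test_sensitivity_sums_to_one_and_limits(self, rng):
        cells = rng.lognormal(0, 1, 200)
        probs = sensitivity_bin_probs(cells, cells.mean(), cells.std())
        assert abs(probs.sum() - 1.0) < 1e-12
        assert np.all(probs >= 0)
        # future far above every baseline cell with tiny SD -> very high
        far = sensitivity_bin_probs(cells, cells.max() * 10 + 5, 1e-6)
        assert far[3] > 1 - 1e-9

    def test_matched_normal_masses(self, rng):
        """Baseline ~ N(0,1) with future N(0,1): interval masses are
        (0.2, 0.4, 0.4, ~0) and directional thirds, to Monte-Carlo
        accuracy."""
        cells = rng.standard_normal(100_000)
        s = sensitivity_bin_probs(cells, 0.0, 1.0)
        np.testing.assert_allclose(s[:3], [0.2, 0.4, 0.4], atol=0.01)
        assert s[3] < 0.01
        d = directional_bin_probs(cells, 0.0, 1.0)
        np.testing.assert_allclose(d, [1 / 3, 1 / 3, 1 / 3], atol=0.01)

    def test_directional_limits_and_sum(self, rng):
        cells = rng.standard_normal(500)
        d = directional_bin_probs(cells, 50.0, 1e-6)
        np.testing.assert_allclose(d, [0.0, 0.0, 1.0], atol=1e-12)
        d2 = directional_bin_probs(cells, 0.3, 0.8)
        assert abs(d2.sum() - 1.0) < 1e-12

    def test_tail_mass_monotone_in_displacement(self, rng):
        cells = rng.standard_normal(1000)
        disps = np.linspace(0, 6, 13)
        pvh = [sensitivity_bin_probs(cells, d, 1.0)[3] for d in disps]
        assert np.all(np.diff(pvh) >= -1e-12)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            sensitivity_bin_probs(np.ones(3), 0.0, 1.0)
        with pytest.raises(ValueError):
            sensitivity_bin_probs(rng.random(10), 0.0, 0.0)


class TestVoteLoglik:
    def test_certain_outcome_has_log_probability_zero(self):
        votes = _votes([300, 0, 0, 0], [12, 0, 0])
        ls, ld = vote_loglik(votes, np.array([1.0, 0, 0, 0]),
                             np.array([1.0, 0, 0]))
        assert ls == 0.0 and ld == 0.0

    def test_two_bin_coin_flip(self):
        assert multinomial_logpmf(np.array([1, 1]), np.array([0.5, 0.5])) == \
            pytest.approx(np.log(0.5))

    def test_zero_probability_bin_with_votes(self):
        assert multinomial_logpmf(np.array([1, 2]), np.array([0.0, 1.0])) == -np.inf

    def test_pmf_normalizes_over_compositions(self, rng):
        """Exhaustive enumeration oracle: the pmf over all compositions of
        n votes into k bins sums to 1, and matches scipy."""
        from scipy.stats import multinomial as sp_multinomial

        for k, n in ((3, 4), (4, 6), (2, 5)):
            p = rng.dirichlet(np.ones(k))
            total = 0.0
            for c in itertools.product(range(n + 1), repeat=k):
                if sum(c) != n:
                    continue
                lp = multinomial_logpmf(np.array(c), p)
                total += np.exp(lp)
                np.testing.assert_allclose(
                    lp, sp_multinomial.logpmf(c, n, p), rtol=1e-10)
            assert abs(total - 1.0) < 1e-10


class TestLogPrior:
    def test_mode_reflection_and_quadratic_form(self, fitted_delta, rng):
        beta, V = fitted_delta.stage2.beta, fitted_delta.stage2.cov
        thetas = sample_candidates(fitted_delta, 5, rng)
        lp = candidate_logprior(thetas, fitted_delta)
        # independent oracle: explicit quadratic form
        Vi = np.linalg.inv(V + 1e-12 * np.eye(len(beta)) * np.trace(V) / len(beta))
        sign, logdet = np.linalg.slogdet(np.linalg.inv(Vi))
        for i in range(5):
            d = thetas[i] - beta
            expected = -0.5 * (d @ Vi @ d + logdet + len(beta) * np.log(2 * np.pi))
            assert lp[i] == pytest.approx(expected, rel=1e-6)
        # mode maximal, reflection symmetric
        lp_beta = candidate_logprior(beta, fitted_delta)[0]
        assert np.all(lp <= lp_beta + 1e-10)
        refl = candidate_logprior(2 * beta - thetas, fitted_delta)
        np.testing.assert_allclose(refl, lp, rtol=1e-8)

    def test_matches_scipy(self, fitted_delta, rng):
        thetas = sample_candidates(fitted_delta, 4, rng)
        ref = multivariate_normal.logpdf(
            thetas, fitted_delta.stage2.beta, fitted_delta.stage2.cov,
            allow_singular=True)
        np.testing.assert_allclose(
            candidate_logprior(thetas, fitted_delta), ref, rtol=1e-6)


class TestPosteriorSelect:
    def _table(self, prior, ls, ld):
        t = pd.DataFrame({"log_prior": prior, "log_lik_sens": ls,
                          "log_lik_dir": ld})
        t["log_posterior"] = t.sum(axis=1)
        return t

    def test_prior_dominated_when_likelihoods_equal(self, rng):
        prior = rng.normal(size=30)
        t = self._table(prior, np.full(30, -3.0), np.full(30, -1.0))
        assert posterior_select(t) == int(np.argmax(prior))

    def test_constant_shift_invariance(self, rng):
        prior, ls, ld = rng.normal(size=(3, 25))
        t1 = self._table(prior, ls, ld)
        t2 = self._table(prior, ls + 42.0, ld)
        assert posterior_select(t1) == posterior_select(t2)

    def test_ties_break_to_lowest_index(self):
        t = self._table(np.zeros(4), np.zeros(4), np.zeros(4))
        assert posterior_select(t) == 0

    def test_all_infinite_rejected(self):
        t = self._table(np.full(3, -np.inf), np.zeros(3), np.zeros(3))
        with pytest.raises(ValueError):
            posterior_select(t)


class TestScoreAndEvaluate:
    def test_probability_vectors_sum_to_one_on_every_candidate(
            self, fitted_delta, envs, rng):
        base, fut = envs
        thetas = sample_candidates(fitted_delta, 100, rng)
        tab = score_candidates(fitted_delta, thetas,
                               _votes([75, 75, 75, 75], [4, 4, 4]),
                               base, fut, FusionConfig(n_candidates=100))
        sens_sum = tab[["p_low", "p_moderate", "p_high", "p_very_high"]].sum(axis=1)
        dir_sum = tab[["p_negative", "p_neutral", "p_positive"]].sum(axis=1)
        np.testing.assert_allclose(sens_sum, 1.0, atol=1e-12)
        np.testing.assert_allclose(dir_sum, 1.0, atol=1e-12)
        np.testing.assert_allclose(
            tab["log_posterior"],
            tab["log_prior"] + tab["log_lik_sens"] + tab["log_lik_dir"],
            rtol=1e-12)

    def test_flat_votes_rank_by_prior(self, fitted_delta, envs, rng):
        """With evenly split votes the posterior ordering of candidates
        correlates strongly with prior density."""
        base, fut = envs
        thetas = sample_candidates(fitted_delta, 1000, rng)
        tab = score_candidates(fitted_delta, thetas,
                               _votes([75, 75, 75, 75], [4, 4, 4]),
                               base, fut, FusionConfig())
        rho = spearmanr(tab["log_posterior"], tab["log_prior"]).statistic
        assert rho > 0.5

    def test_map_theta_equal_beta_gives_zero_differences(
            self, fitted_delta, survey):
        test = survey[(survey["year"] > 2011) & (survey["season"] == "fall")]
        out = fused_evaluate(fitted_delta, fitted_delta.stage2.beta, test)
        assert out["d_r"] == 0.0
        assert out["d_crmse_norm"] == 0.0
        assert out["d_sd_ratio"] == 0.0
        assert out["auc_sdm"] == out["auc_combined"]

    def test_evaluate_matches_validation_module(self, fitted_delta, survey, rng):
        from sdmfuse.delta import predict_presence
        from sdmfuse.validation import taylor_stats

        test = survey[(survey["year"] > 2011) & (survey["season"] == "fall")]
        theta = sample_candidates(fitted_delta, 1, rng)[0]
        out = fused_evaluate(fitted_delta, theta, test)
        env = {"sst": test["sst"].to_numpy(), "depth": test["depth_m"].to_numpy()}
        p1 = predict_presence(fitted_delta, env, warn_extrapolation=False)
        pred = p1 * np.exp(fitted_delta.stage2.predict(
            env, beta=theta, warn_extrapolation=False))
        ref = taylor_stats(test["biomass_kg"].to_numpy(), pred)
        assert out["r_combined"] == pytest.approx(ref.r)
        assert out["sd_ratio_combined"] == pytest.approx(ref.sd_ratio)

    def test_empty_test_set_rejected(self, fitted_delta, survey):
        with pytest.raises(ValueError):
            fused_evaluate(fitted_delta, fitted_delta.stage2.beta,
                           survey.head(0))
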