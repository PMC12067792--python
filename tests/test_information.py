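import numpy as np
import pytest

import cdmhier as ch
from cdmhier.information import (
    _gradient,
    covariance,
    obs_information,
    score_contributions,
    xpd_information,
)
from cdmhier.model import pattern_loglik
from scipy.special import logsumexp
from tests.conftest import small_interior_instance


def _loglik_at(fit, X, gamma):
    from cdmhier.information import _unpack_gamma
    item_probs, pi_s = _unpack_gamma(fit, gamma)
    P = np.vstack([item_probs[j][fit.group_maps[j]] for j in range(fit.Q.shape[0])])
    logp = pattern_loglik(X, P)
    return logsumexp(logp + np.log(np.maximum(pi_s, 1e-300)), axis=1)


@pytest.fixture(scope="module")
def interior_fit():
    X, Q = small_interior_instance(seed=21, N=120)
    return ch.fit(X, Q), X


class TestScores:
    def test_column_sums_vanish_at_interior_mle(self, interior_fit):
        """First-order condition: zero gradient in every coordinate that is
        away from the probability bounds (bound-clipped coordinates may carry
        a one-sided gradient)."""
        fit, X = interior_fit
        gamma = fit.gamma()
        interior = (gamma > 2e-4) & (gamma < 1 - 2e-4)
        assert interior.sum() >= len(gamma) - 3
        colsums = score_contributions(fit, X).sum(axis=0)
        assert np.abs(colsums[interior]).max() < 1e-3

    def test_matches_finite_difference_per_examinee(self, interior_fit):
        """Row i of the score matrix is the gradient of examinee i's
        log-likelihood contribution."""
        fit, X = interior_fit
        gamma = fit.gamma()
        scores = score_contributions(fit, X)
        rng = np.random.default_rng(0)
        for k in rng.choice(len(gamma), size=8, replace=False):
            h = 1e-6
            gp = gamma.copy(); gp[k] += h
            gm = gamma.copy(); gm[k] -= h
            fd = (_loglik_at(fit, X, gp) - _loglik_at(fit, X, gm)) / (2 * h)
            assert np.allclose(scores[:, k], fd, atol=1e-4)

    def test_gradient_shortcut_equals_score_sums(self, interior_fit):
        fit, X = interior_fit
        g = _gradient(fit, X, fit.gamma())
        assert np.allclose(g, score_contributions(fit, X).sum(axis=0), atol=1e-10)


class TestXpd:
    def test_single_examinee_rank_one(self, interior_fit):
        fit, X = interior_fit
        info = xpd_information(score_contributions(fit, X[:1]))
        assert np.linalg.matrix_rank(info, tol=1e-10) <= 1

    def test_psd_and_permutation_invariant(self, interior_fit):
        fit, X = interior_fit
        s = score_contributions(fit, X)
        info = xpd_information(s)
        assert np.allclose(info, info.T)
        assert np.linalg.eigvalsh(info).min() > -1e-8
        perm = np.random.default_rng(1).permutation(len(s))
        assert np.allclose(info, xpd_information(s[perm]))


class TestObs:
    def test_matches_brute_force_hessian(self, interior_fit):
        """Closed-form observed information equals the negative
        finite-difference Hessian of the total log-likelihood."""
        fit, X = interior_fit
        gamma = fit.gamma()
        info = obs_information(fit, X)
        rng = np.random.default_rng(2)
        idx = rng.choice(len(gamma), size=6, replace=False)
        h = 1e-5
        for a in idx:
            ga_p = gamma.copy(); ga_p[a] += h
            ga_m = gamma.copy(); ga_m[a] -= h
            col = -(_gradient(fit, X, ga_p) - _gradient(fit, X, ga_m)) / (2 * h)
            assert np.allclose(info[:, a], col, atol=1e-3 * max(1, np.abs(col).max()))

    def test_information_identity_large_n(self):
        """Under a correctly specified model Obs ~ XPD, and the relative
        discrepancy shrinks with the sample size."""
        dists = []
        for N in (500, 4000):
            rng = np.random.default_rng(100 + N)
            Q = np.array([[1, 0], [0, 1], [1, 1], [1, 0], [0, 1], [1, 1]])
            params = ch.gen_item_params(Q, "moderate")
            pos = rng.integers(0, 4, size=N)
            X = ch.gen_responses(pos, Q, params, rng)
            fit = ch.fit(X, Q)
            xpd = xpd_information(score_contributions(fit, X))
            obs = obs_information(fit, X)
            dists.append(np.linalg.norm(obs - xpd) / np.linalg.norm(xpd))
        assert dists[1] < dists[0]
        assert dists[1] < 0.1


class TestCovariance:
    def test_identity_information(self, interior_fit):
        fit, _ = interior_fit
        cov = covariance(np.eye(fit.npar), "XPD", fit)
        assert np.allclose(cov.cov, np.eye(fit.npar))
        assert cov.rank == fit.npar

    def test_bernoulli_variance_with_separated_classes(self):
        """With near-deterministic items the examinees are cleanly
        classified, and the variance of an item probability collapses to the
        textbook binomial p(1-p)/n of its group count."""
        rng = np.random.default_rng(8)
        N, J = 1500, 12
        Q = np.tile(np.eye(2, dtype=int), (J // 2, 1))
        params = [np.array([0.02, 0.96]) for _ in range(J)]
        pos = rng.integers(0, 4, size=N)
        X = ch.gen_responses(pos, Q, params, rng)
        fit = ch.fit(X, Q)
        cov = covariance(xpd_information(score_contributions(fit, X)), "XPD", fit)
        sp = fit.space
        # group counts: attribute-1 masters for item 0
        n1 = sum(fit.posterior[:, l].sum() for l in range(sp.L)
                 if sp.patterns[l][0] == 1)
        p_hat = fit.item_probs[0][1]
        var_idx = 1  # ('item', 0, 1)
        assert fit.param_index[var_idx] == ("item", 0, 1)
        assert cov.cov[var_idx, var_idx] == pytest.approx(
            p_hat * (1 - p_hat) / n1, rel=0.25)

    def test_multinomial_limit_of_structural_block(self):
        """Perfectly informative items: Sigma_pipi approaches the multinomial
        covariance (diag(pi) - pi pi') / N on the free classes."""
        rng = np.random.default_rng(12)
        N = 2000
        Q = np.tile(np.eye(2, dtype=int), (6, 1))
        params = [np.array([0.005, 0.99]) for _ in range(12)]
        pos = rng.integers(0, 4, size=N)
        X = ch.gen_responses(pos, Q, params, rng)
        fit = ch.fit(X, Q)
        cov = covariance(xpd_information(score_contributions(fit, X)), "XPD", fit)
        pi = fit.pi
        target = (np.diag(pi) - np.outer(pi, pi))[:3, :3] / N
        assert np.allclose(cov.sigma_pp, target, atol=0.3 * np.abs(target).max())

    def test_structural_block_matches_param_index(self, interior_fit):
        fit, X = interior_fit
        cov = covariance(xpd_information(score_contributions(fit, X)), "XPD", fit)
        ns = fit.n_struct_params
        tags = cov.param_index[-ns:]
        assert all(t[0] == "pi" for t in tags)
        assert np.allclose(cov.sigma_pp, cov.cov[-ns:, -ns:])

    def test_variance_shrinks_like_one_over_n(self):
        """log-log regression of the mean structural variance on N has slope
        close to -1."""
        Ns, vars_ = [400, 800, 1600, 3200], []
        Q = np.array([[1, 0], [0, 1], [1, 1], [1, 0], [0, 1], [1, 1]])
        params = ch.gen_item_params(Q, "high")
        for N in Ns:
            rng = np.random.default_rng(N)
            pos = rng.integers(0, 4, size=N)
            X = ch.gen_responses(pos, Q, params, rng)
            fit = ch.fit(X, Q)
            cov = covariance(xpd_information(score_contributions(fit, X)), "XPD", fit)
            vars_.append(np.diag(cov.sigma_pp).mean())
        slope = np.polyfit(np.log(Ns), np.log(vars_), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.35)

    def test_boundary_structural_parameters_reported_fixed(self, sim_k3, sat_fit_k3):
        cov = covariance(obs_information(sat_fit_k3, sim_k3["X"]), "Obs", sat_fit_k3)
        boundary = (sat_fit_k3.pi[sat_fit_k3.support[:-1]] <= 1e-12)
        if boundary.any():
            assert any("boundary" in w for w in cov.warnings_)
            ns = sat_fit_k3.n_struct_params
            for m in np.flatnonzero(boundary):
                assert np.allclose(cov.sigma_pp[m], 0.0)
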