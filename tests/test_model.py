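import numpy as np
import pytest
from scipy.special import expit, logit

import cdmhier as ch
from cdmhier.model import (
    hdcm_prob,
    identity_prob,
    item_subsets,
    lcdm_prob,
    marginal_loglik,
    pattern_loglik,
    prob_table,
    reduced_groups,
    retained_subsets,
    validate_qmatrix,
)


class TestLcdmProb:
    def test_all_zero_coefficients_give_half(self):
        assert lcdm_prob([0, 0, 0, 0], (1, 1), (0, 1)) == pytest.approx(0.5)

    def test_two_attribute_item_with_symmetric_effects(self):
        """Intercept logit(0.1), three equal effects: full mastery hits 0.9,
        no mastery 0.1, partial mastery logistic(-0.7324) ~ 0.3246."""
        lam0 = logit(0.1)
        eff = (logit(0.9) - logit(0.1)) / 3
        lam = [lam0, eff, eff, eff]
        assert lcdm_prob(lam, (1, 1), (1, 1)) == pytest.approx(0.9, abs=1e-12)
        assert lcdm_prob(lam, (1, 1), (0, 0)) == pytest.approx(0.1, abs=1e-12)
        assert lcdm_prob(lam, (1, 1), (1, 0)) == pytest.approx(0.3246, abs=1e-4)

    def test_kernel_expansion_two_attributes(self):
        """The kernel is lam0 + lam1 a1 + lam2 a2 + lam12 a1 a2 for q=(1,1)."""
        rng = np.random.default_rng(0)
        lam = rng.normal(size=4)
        for a1 in (0, 1):
            for a2 in (0, 1):
                eta = lam[0] + lam[1] * a1 + lam[2] * a2 + lam[3] * a1 * a2
                assert lcdm_prob(lam, (1, 1), (a1, a2)) == pytest.approx(expit(eta))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            lcdm_prob([0, 0], (1, 1), (1,))


class TestHdcmProb:
    def test_nested_main_effect_removed(self):
        """Under 1 -> 2 with q=(1,1) the kernel is lam0 + lam1 a1 + lam12 a1 a2:
        the (1,0) pattern activates only the first main effect."""
        h = ch.AttributeHierarchy(2, frozenset({(1, 2)}))
        lam = [-1.0, 2.0, 0.7, 0.5]
        assert hdcm_prob(lam, (1, 1), (1, 0), h) == pytest.approx(expit(-1.0 + 2.0))
        # the nested main effect lam2 contributes nowhere
        assert hdcm_prob(lam, (1, 1), (0, 1), h) == pytest.approx(expit(-1.0))
        assert hdcm_prob(lam, (1, 1), (1, 1), h) == pytest.approx(expit(-1.0 + 2.0 + 0.5))

    def test_retained_coefficients_zero_gives_half(self):
        h = ch.AttributeHierarchy(2, frozenset({(1, 2)}))
        lam = [0.0, 0.0, 123.0, 0.0]  # only the removed effect is nonzero
        for a in [(0, 0), (1, 0), (0, 1), (1, 1)]:
            assert hdcm_prob(lam, (1, 1), a, h) == pytest.approx(0.5)

    @pytest.mark.parametrize("K", [2, 3, 4])
    def test_equals_saturated_with_removed_effects_zeroed(self, K):
        rng = np.random.default_rng(K)
        pairs = frozenset((k, k + 1) for k in range(1, K))
        h = ch.AttributeHierarchy(K, pairs, "linear")
        q = np.ones(K, dtype=int)
        subsets = item_subsets(q)
        lam = rng.normal(size=len(subsets) + 1)
        kept = set(retained_subsets(q, h))
        lam_zeroed = lam.copy()
        for s, S in enumerate(subsets, start=1):
            if S not in kept:
                lam_zeroed[s] = 0.0
        for alpha in ch.enumerate_patterns(K).patterns:
            assert hdcm_prob(lam, q, alpha, h) == pytest.approx(
                lcdm_prob(lam_zeroed, q, alpha))


class TestIdentityProb:
    def test_quality_endpoints(self):
        q = (1, 1, 1)
        delta = np.concatenate([[0.1], np.full(7, 0.8 / 7)])
        assert identity_prob(delta, q, (0, 0, 0)) == pytest.approx(0.1)
        assert identity_prob(delta, q, (1, 1, 1)) == pytest.approx(0.9)

    def test_partial_mastery_counts_active_subsets(self):
        """alpha=(1,1,0) on a three-attribute item activates two main effects
        and one two-way interaction: 0.1 + 3 * 0.8/7."""
        delta = np.concatenate([[0.1], np.full(7, 0.8 / 7)])
        assert identity_prob(delta, (1, 1, 1), (1, 1, 0)) == pytest.approx(
            0.1 + 3 * 0.8 / 7)

    def test_invalid_probability_raises(self):
        with pytest.raises(ValueError, match="outside"):
            identity_prob([0.9, 0.9], (1, 0), (1, 0))


class TestMarginalLoglik:
    def test_single_observation(self):
        # one examinee, one item: 0.5 * 0.2 + 0.5 * 0.8 = 0.5
        P = np.array([[0.2, 0.8]])
        assert marginal_loglik([[1]], P, [0.5, 0.5]) == pytest.approx(np.log(0.5))

    def test_additivity_over_examinees(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(0.2, 0.8, size=(4, 3))
        pi = np.array([0.5, 0.3, 0.2])
        X = rng.integers(0, 2, size=(10, 4))
        total = marginal_loglik(X, P, pi)
        parts = sum(marginal_loglik(X[i:i + 1], P, pi) for i in range(10))
        assert total == pytest.approx(parts)

    def test_against_naive_double_loop(self):
        rng = np.random.default_rng(7)
        N, J, L = 20, 5, 8
        P = rng.uniform(0.05, 0.95, size=(J, L))
        pi = rng.dirichlet(np.ones(L))
        X = rng.integers(0, 2, size=(N, J))
        naive = 0.0
        for i in range(N):
            mix = 0.0
            for l in range(L):
                lik = 1.0
                for j in range(J):
                    lik *= P[j, l] if X[i, j] else 1 - P[j, l]
                mix += pi[l] * lik
            naive += np.log(mix)
        assert marginal_loglik(X, P, pi) == pytest.approx(naive)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            marginal_loglik([[2]], np.array([[0.5, 0.5]]), [0.5, 0.5])


def test_qmatrix_validation():
    with pytest.raises(ValueError, match="binary"):
        validate_qmatrix([[1, 2], [1, 0]])
    with pytest.raises(ValueError, match="no required attribute"):
        validate_qmatrix([[1, 0], [0, 0]])
    Q = validate_qmatrix([[1, 0], [1, 1]])
    assert Q.dtype == np.int8


def test_reduced_groups_partition_patterns():
    sp = ch.enumerate_patterns(3)
    gmap, gp = reduced_groups((1, 0, 1), sp)
    assert len(gp) == 4
    # patterns agreeing on attributes 1 and 3 share a group
    for l1 in range(8):
        for l2 in range(8):
            same = (sp.patterns[l1][[0, 2]] == sp.patterns[l2][[0, 2]]).all()
            assert (gmap[l1] == gmap[l2]) == same


def test_prob_table_monotone_for_simulation_parameterization():
    """With positive equal increments, mastering more required attributes
    never lowers the response probability."""
    rng = np.random.default_rng(3)
    Q = ch.gen_qmatrix(30, 3, rng)
    from cdmhier.simulate import response_prob_table
    table = response_prob_table(Q, ch.gen_item_params(Q, "moderate"))
    sp = ch.enumerate_patterns(3)
    assert table.min() >= 0 and table.max() <= 1
    for l1, p1 in enumerate(sp.patterns):
        for l2, p2 in enumerate(sp.patterns):
            if (p1 <= p2).all():
                assert (table[:, l1] <= table[:, l2] + 1e-12).all()
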