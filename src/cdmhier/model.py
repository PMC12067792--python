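"""Item response functions and the observed-data marginal likelihood.

The saturated model is a restricted latent class model: an examinee belongs to
one of the L = 2**K mastery patterns with structural probability ``pi_l``, and
answers item j correctly with a probability that depends on the pattern only
through the attributes the item requires (its Q-matrix row ``q_j``).  Patterns
that agree on the required attributes therefore form *reduced latent groups*,
and the package's canonical internal parameterization is the vector of
group-conditional success probabilities ``P_{jg}`` per item.  Two standard
link functions are provided as views onto those probabilities:

* the logit link (log-linear model with main and interaction effects
  ``lambda``), and
* the identity link (probability-scale baseline and increments ``delta``),
  which is the estimation default here.

Under an attribute hierarchy the model keeps only the groups reachable from
permissible patterns; in the logit view this is equivalent to fixing at zero
every effect whose attribute subset is not itself a reachable projection
(e.g., with q = (1,1) and 1 -> 2 the main effect of the nested attribute 2 is
removed and the kernel is lambda_0 + lambda_1 a_1 + lambda_12 a_1 a_2).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import expit, logsumexp

from .hierarchy import AttributeHierarchy, permissible_mask
from .patterns import PatternSpace, enumerate_patterns

__all__ = [
    "validate_qmatrix",
    "item_subsets",
    "reduced_groups",
    "lcdm_prob",
    "hdcm_prob",
    "identity_prob",
    "prob_table",
    "marginal_loglik",
]

PROB_EPS = 1e-10  # clamp inside likelihood evaluation to avoid log(0)


def validate_qmatrix(Q) -> np.ndarray:
    """Check and coerce a J x K binary Q-matrix (every row nonzero)."""
    Q = np.asarray(Q)
    if Q.ndim != 2:
        raise ValueError("Q must be a 2-d items-by-attributes matrix")
    if not np.isin(Q, (0, 1)).all():
        raise ValueError("Q entries must be binary")
    if (Q.sum(axis=1) == 0).any():
        bad = np.flatnonzero(Q.sum(axis=1) == 0) + 1
        raise ValueError(f"Q rows with no required attribute: items {list(bad)}")
    return Q.astype(np.int8)


def item_subsets(q_row) -> list[tuple[int, ...]]:
    """Nonempty subsets of the item's required attributes (1-based), ordered
    by size then lexicographically: the lambda/delta effect order."""
    req = [k + 1 for k, v in enumerate(q_row) if v == 1]
    out: list[tuple[int, ...]] = []
    for r in range(1, len(req) + 1):
        out.extend(combinations(req, r))
    return out


def reduced_groups(q_row, space: PatternSpace) -> tuple[np.ndarray, np.ndarray]:
    """Map full patterns to the item's reduced latent groups.

    Returns ``(group_of, group_patterns)`` where ``group_of[l]`` is the
    0-based group index of canonical pattern position ``l`` and
    ``group_patterns`` is the ``(2**K_j, K_j)`` array of group-defining
    sub-patterns on the required attributes, in canonical order.
    """
    req = np.flatnonzero(np.asarray(q_row) == 1)
    sub_space = enumerate_patterns(len(req))
    proj = space.patterns[:, req]
    group_of = np.array([sub_space.position(row) - 1 for row in proj], dtype=np.intp)
    return group_of, sub_space.patterns


def _check_alpha(q_row, alpha):
    q_row = np.asarray(q_row)
    alpha = np.asarray(alpha)
    if q_row.shape != alpha.shape:
        raise ValueError(f"q row length {q_row.size} != pattern length {alpha.size}")
    return q_row, alpha


def lcdm_prob(lam, q_row, alpha) -> float:
    """Logit-link item response probability.

    ``lam`` holds the intercept followed by one coefficient per nonempty
    subset of required attributes in :func:`item_subsets` order
    (``2**K_j - 1`` effects).  The kernel adds every effect whose attribute
    subset is fully mastered; the probability is ``expit`` of the kernel.
    """
    q_row, alpha = _check_alpha(q_row, alpha)
    subsets = item_subsets(q_row)
    lam = np.asarray(lam, dtype=float)
    if lam.size != len(subsets) + 1:
        raise ValueError(f"expected {len(subsets) + 1} coefficients, got {lam.size}")
    eta = lam[0]
    for coef, S in zip(lam[1:], subsets):
        if all(alpha[k - 1] == 1 for k in S):
            eta += coef
    return float(expit(eta))


def retained_subsets(q_row, h: AttributeHierarchy) -> list[tuple[int, ...]]:
    """Effect subsets the hierarchical model keeps for this item: those that
    are themselves projections of permissible patterns onto the required
    attributes."""
    space = enumerate_patterns(h.K)
    req = np.flatnonzero(np.asarray(q_row) == 1)
    perm = space.patterns[permissible_mask(h, space)]
    reachable = {tuple(int(v) for v in row) for row in perm[:, req]}
    kept = []
    for S in item_subsets(q_row):
        proj = tuple(1 if (k + 1) in S else 0 for k in req)
        if proj in reachable:
            kept.append(S)
    return kept


def hdcm_prob(lam, q_row, alpha, h: AttributeHierarchy) -> float:
    """Hierarchical (reduced) logit-link probability: the saturated kernel
    with hierarchy-removed effects fixed at zero.  Total in ``alpha`` — the
    value is defined for impermissible patterns too."""
    q_row, alpha = _check_alpha(q_row, alpha)
    subsets = item_subsets(q_row)
    lam = np.asarray(lam, dtype=float)
    if lam.size != len(subsets) + 1:
        raise ValueError(f"expected {len(subsets) + 1} coefficients, got {lam.size}")
    kept = set(retained_subsets(q_row, h))
    eta = lam[0]
    for coef, S in zip(lam[1:], subsets):
        if S in kept and all(alpha[k - 1] == 1 for k in S):
            eta += coef
    return float(expit(eta))


def identity_prob(delta, q_row, alpha) -> float:
    """Identity-link probability: baseline ``delta[0]`` plus the increments of
    every fully mastered required-attribute subset.  Raises if the result
    leaves [0, 1]."""
    q_row, alpha = _check_alpha(q_row, alpha)
    subsets = item_subsets(q_row)
    delta = np.asarray(delta, dtype=float)
    if delta.size != len(subsets) + 1:
        raise ValueError(f"expected {len(subsets) + 1} parameters, got {delta.size}")
    p = delta[0]
    for inc, S in zip(delta[1:], subsets):
        if all(alpha[k - 1] == 1 for k in S):
            p += inc
    if not -1e-12 <= p <= 1 + 1e-12:
        raise ValueError(f"identity-link probability {p:.4f} outside [0, 1]")
    return float(min(max(p, 0.0), 1.0))


def group_probs_from_identity(delta, q_row) -> np.ndarray:
    """Group-conditional success probabilities implied by identity-link
    parameters, over the item's reduced groups in canonical sub-pattern
    order."""
    _, group_patterns = reduced_groups(q_row, enumerate_patterns(len(q_row)))
    req = np.flatnonzero(np.asarray(q_row) == 1)
    out = np.empty(len(group_patterns))
    for g, sub in enumerate(group_patterns):
        alpha = np.zeros(len(q_row), dtype=int)
        alpha[req] = sub
        out[g] = identity_prob(delta, q_row, alpha)
    return out


def prob_table(item_group_probs, group_maps, L: int) -> np.ndarray:
    """Expand per-item group probabilities to the J x L class-conditional
    success probability table."""
    J = len(item_group_probs)
    P = np.empty((J, L))
    for j in range(J):
        P[j] = np.asarray(item_group_probs[j])[group_maps[j]]
    return P


def marginal_loglik(X, P, pi) -> float:
    """Observed-data marginal log-likelihood of a latent class model.

    ``sum_i log sum_l pi_l prod_j P_jl^x_ij (1 - P_jl)^(1 - x_ij)`` with the
    class-conditional probabilities clamped to ``[1e-10, 1 - 1e-10]``.
    """
    X = np.asarray(X)
    pi = np.asarray(pi, dtype=float)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("responses must be binary")
    logp = pattern_loglik(X, P)
    with np.errstate(divide="ignore"):
        logpi = np.where(pi > 0, np.log(np.maximum(pi, PROB_EPS)), -np.inf)
    return float(logsumexp(logp + logpi, axis=1).sum())


def pattern_loglik(X, P) -> np.ndarray:
    """N x L matrix of log P(x_i | class l) given the J x L probability
    table."""
    X = np.asarray(X, dtype=float)
    Pc = np.clip(np.asarray(P, dtype=float), PROB_EPS, 1 - PROB_EPS)
    logP = np.log(Pc)
    log1mP = np.log1p(-Pc)
    return X @ (logP - log1mP) + log1mP.sum(axis=0)
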