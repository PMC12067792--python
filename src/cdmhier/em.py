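"""Marginal maximum likelihood estimation by EM.

The saturated model and its hierarchy-restricted (HDCM-style) reduction are
both estimated in the canonical probability parameterization: per item, one
success probability per reduced latent group; plus the structural vector
``pi`` over the admitted pattern classes.  The E-step computes posterior
class memberships by Bayes' rule; the identity-link M-step is closed form
(expected successes over expected membership per group, class-mean update for
``pi``).  Because the logit-link item parameters are a smooth bijection of
the group probabilities (triangular Moebius inversion of the logits), the
same EM delivers the maximum likelihood estimates for either link; the link
only selects the reported item-parameter view.

Under a hierarchy restriction the impermissible structural parameters are
fixed at exactly zero and each item keeps only the latent groups reachable
from permissible patterns (the generalization of removing nested main
effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit, logsumexp

from .hierarchy import AttributeHierarchy, permissible_mask
from .model import (
    item_subsets,
    pattern_loglik,
    reduced_groups,
    retained_subsets,
    validate_qmatrix,
)
from .patterns import PatternSpace, enumerate_patterns

__all__ = ["ModelFit", "fit", "fit_nested", "e_step", "m_step"]

PI_FLOOR = 0.0      # structural estimates may legitimately reach the boundary
P_BOUND = 1e-4      # item probabilities confined to [P_BOUND, 1 - P_BOUND]


@dataclass
class ModelFit:
    """A fitted (possibly hierarchy-restricted) diagnostic classification
    model.

    ``item_probs[j]`` holds item j's group success probabilities (all
    ``2**K_j`` groups for the saturated model, only the reachable groups under
    a restriction); ``pi`` is the full length-L structural vector with exact
    zeros at impermissible positions; ``posterior`` is N x L.  ``param_index``
    labels the free-parameter vector gamma = (item probabilities, free
    structural probabilities) used by the information-matrix routines; the
    reference class closing the sum-to-one constraint is the all-ones pattern.
    """

    Q: np.ndarray
    link: str
    hierarchy: AttributeHierarchy | None
    space: PatternSpace
    support: np.ndarray                  # 0-based admitted class positions
    group_maps: list                     # per item: support-class -> group idx
    group_patterns: list                 # per item: group defining sub-patterns
    item_probs: list
    pi: np.ndarray
    loglik: float
    posterior: np.ndarray
    n_iter: int
    converged: bool
    warnings_: list = field(default_factory=list)

    @property
    def n_item_params(self) -> int:
        return int(sum(len(p) for p in self.item_probs))

    @property
    def n_struct_params(self) -> int:
        return int(len(self.support) - 1)

    @property
    def npar(self) -> int:
        return self.n_item_params + self.n_struct_params

    @property
    def param_index(self) -> list:
        """Labels for gamma: ('item', j, g) then ('pi', l) with l the 0-based
        canonical position of each free structural parameter."""
        idx = [("item", j, g) for j, p in enumerate(self.item_probs) for g in range(len(p))]
        idx += [("pi", int(l)) for l in self.support[:-1]]
        return idx

    def gamma(self) -> np.ndarray:
        """Free-parameter vector (item probabilities, free pi)."""
        return np.concatenate([np.concatenate(self.item_probs), self.pi[self.support[:-1]]])

    def item_params(self, j: int) -> dict:
        """Item j's parameters in the requested link view.

        Identity link: baseline and per-subset increments.  Logit link:
        intercept and per-subset effects (restricted models report only the
        retained subsets).  Effect order follows :func:`item_subsets`.
        """
        probs = np.asarray(self.item_probs[j])
        subs = (
            item_subsets(self.Q[j])
            if self.hierarchy is None or self.hierarchy.is_empty
            else retained_subsets(self.Q[j], self.hierarchy)
        )
        # group g's kernel value accumulates the coefficients of retained
        # subsets contained in the group pattern; invert triangularly
        gp = self.group_patterns[j]
        req = np.flatnonzero(self.Q[j] == 1)
        contains = np.zeros((len(gp), len(subs) + 1))
        contains[:, 0] = 1.0
        for s, S in enumerate(subs, start=1):
            proj = np.array([1 if (k + 1) in S else 0 for k in req])
            contains[:, s] = (gp >= proj).all(axis=1)
        if self.link == "logit":
            coefs = np.linalg.solve(contains, logit(np.clip(probs, P_BOUND, 1 - P_BOUND)))
            return {"intercept": float(coefs[0]),
                    "effects": dict(zip(subs, coefs[1:].tolist()))}
        coefs = np.linalg.solve(contains, probs)
        return {"baseline": float(coefs[0]),
                "increments": dict(zip(subs, coefs[1:].tolist()))}

    def map_patterns(self) -> np.ndarray:
        """Posterior-mode (MAP) pattern position per examinee, 0-based; ties
        break to the lowest canonical position."""
        return np.argmax(self.posterior, axis=1)

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        return {
            "link": self.link,
            "hierarchy": None if self.hierarchy is None else {
                "K": self.hierarchy.K,
                "name": self.hierarchy.name,
                "prerequisites": sorted(self.hierarchy.prerequisites),
            },
            "loglik": self.loglik,
            "npar": self.npar,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "pi": self.pi.tolist(),
            "item_probs": [p.tolist() for p in self.item_probs],
            "warnings": list(self.warnings_),
        }


def e_step(X, P, pi_support) -> tuple[np.ndarray, float]:
    """Posterior memberships and the current marginal log-likelihood.

    ``P`` is the J x S probability table over the admitted classes and
    ``pi_support`` the matching structural probabilities.  Posterior entry
    (i, s) is proportional to ``pi_s * P(x_i | class s)``; rows sum to one.
    """
    logp = pattern_loglik(X, P)
    logw = logp + np.log(np.maximum(pi_support, 1e-300))
    norm = logsumexp(logw, axis=1, keepdims=True)
    post = np.exp(logw - norm)
    return post, float(norm.sum())


def m_step(X, post, group_maps, item_probs_old, pi_floor=PI_FLOOR):
    """Closed-form identity-link M-step.

    Each group probability becomes expected successes over expected
    membership (kept at its previous value, with a warning flag, when the
    expected membership is numerically empty); ``pi`` becomes the posterior
    column means, floored and renormalized.
    """
    X = np.asarray(X, dtype=float)
    n_bar = post.sum(axis=0)                       # expected class counts
    succ = post.T @ X                              # S x J expected successes
    item_probs = []
    empty_items = []
    for j, gmap in enumerate(group_maps):
        G = len(item_probs_old[j])
        memb = np.bincount(gmap, weights=n_bar, minlength=G)
        hits = np.bincount(gmap, weights=succ[:, j], minlength=G)
        p = np.array(item_probs_old[j], dtype=float)
        ok = memb > 1e-10
        p[ok] = np.clip(hits[ok] / memb[ok], P_BOUND, 1 - P_BOUND)
        if not ok.all():
            empty_items.append(j)
        item_probs.append(p)
    pi_support = np.maximum(n_bar / len(X), pi_floor)
    total = pi_support.sum()
    if total <= 0:
        raise FloatingPointError("posterior mass vanished in the M-step")
    pi_support = pi_support / total
    return item_probs, pi_support, empty_items


def _init_item_probs(group_patterns):
    """Deterministic monotone ramp from 0.2 to 0.8 in mastery count."""
    out = []
    for gp in group_patterns:
        kj = gp.shape[1]
        out.append(0.2 + 0.6 * gp.sum(axis=1) / kj)
    return out


def fit(
    X,
    Q,
    link: str = "identity",
    hierarchy: AttributeHierarchy | None = None,
    max_iter: int = 20000,
    tol_param: float = 1e-9,
    tol_loglik: float = 0.0,
    init_item_probs=None,
    init_pi=None,
) -> ModelFit:
    """Fit the saturated model (``hierarchy=None`` or empty) or its
    hierarchy-restricted reduction by EM.

    Convergence is declared when the largest absolute parameter change drops
    below ``tol_param`` (or, if ``tol_loglik`` > 0, when the relative
    log-likelihood change drops below it); otherwise the fit is returned
    flagged non-converged after ``max_iter`` iterations.  The default
    parameter tolerance is deliberately strict: structural probabilities of
    latent classes the data exclude decay geometrically, and the
    information-matrix routines rely on such estimates having effectively
    reached their boundary (zero) rather than stalling at the stopping
    threshold.  Iterations are cheap (two matrix products), so the strict
    tolerance costs little.
    """
    X = np.asarray(X)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("responses must be binary")
    Q = validate_qmatrix(Q)
    if link not in ("identity", "logit"):
        raise ValueError(f"unknown link {link!r}")
    N, J = X.shape
    if Q.shape[0] != J:
        raise ValueError(f"X has {J} items but Q has {Q.shape[0]} rows")
    K = Q.shape[1]
    space = enumerate_patterns(K)
    restricted = hierarchy is not None and not hierarchy.is_empty
    if restricted and hierarchy.K != K:
        raise ValueError("hierarchy and Q disagree on K")

    if restricted:
        support = np.flatnonzero(permissible_mask(hierarchy, space))
    else:
        support = np.arange(space.L)

    # reduced groups; under a restriction keep only reachable groups and
    # renumber them in canonical sub-pattern order
    group_maps, group_patterns = [], []
    for j in range(J):
        gmap_full, gp_full = reduced_groups(Q[j], space)
        gmap = gmap_full[support]
        if restricted:
            reach = np.unique(gmap)
            renum = -np.ones(len(gp_full), dtype=np.intp)
            renum[reach] = np.arange(len(reach))
            gmap = renum[gmap]
            gp = gp_full[reach]
        else:
            gp = gp_full
        group_maps.append(gmap)
        group_patterns.append(gp)

    item_probs = [np.asarray(p, dtype=float) for p in init_item_probs] \
        if init_item_probs is not None else _init_item_probs(group_patterns)
    pi_support = np.asarray(init_pi, dtype=float) if init_pi is not None \
        else np.full(len(support), 1.0 / len(support))
    pi_support = pi_support / pi_support.sum()

    S = len(support)
    loglik = -np.inf
    converged = False
    warn_items: set[int] = set()
    it = 0
    for it in range(1, max_iter + 1):
        P = np.empty((J, S))
        for j in range(J):
            P[j] = item_probs[j][group_maps[j]]
        post, ll = e_step(X, P, pi_support)
        new_item_probs, new_pi, empty_items = m_step(X, post, group_maps, item_probs)
        warn_items.update(empty_items)
        delta = max(
            max(np.max(np.abs(a - b)) for a, b in zip(new_item_probs, item_probs)),
            np.max(np.abs(new_pi - pi_support)),
        )
        rel_ll = abs(ll - loglik) / max(abs(ll), 1.0)
        item_probs, pi_support, loglik = new_item_probs, new_pi, ll
        if delta < tol_param or (tol_loglik > 0 and rel_ll < tol_loglik):
            converged = True
            break

    # final E-step at the converged parameters
    P = np.empty((J, S))
    for j in range(J):
        P[j] = item_probs[j][group_maps[j]]
    post, loglik = e_step(X, P, pi_support)

    pi_full = np.zeros(space.L)
    pi_full[support] = pi_support
    post_full = np.zeros((N, space.L))
    post_full[:, support] = post

    notes = []
    if warn_items:
        items = sorted(int(j) + 1 for j in warn_items)
        notes.append(f"empty expected membership left parameters at previous value: items {items}")
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
    if not converged:
        notes.append(f"EM did not converge in {max_iter} iterations")

    return ModelFit(
        Q=Q, link=link,
        hierarchy=hierarchy if restricted else None,
        space=space, support=support,
        group_maps=group_maps, group_patterns=group_patterns,
        item_probs=item_probs, pi=pi_full, loglik=loglik,
        posterior=post_full, n_iter=it, converged=converged,
        warnings_=notes,
    )


def fit_nested(
    X,
    Q,
    hierarchy: AttributeHierarchy,
    link: str = "identity",
    **fit_kwargs,
) -> tuple[ModelFit, ModelFit]:
    """Fit the saturated and hierarchy-restricted models on the same data
    with the nesting guarantee needed by the likelihood-ratio test.

    EM can stop in a local optimum; if the saturated fit's log-likelihood
    falls below the restricted fit's (which the nesting forbids at the global
    optima), the saturated model is refitted starting from the restricted
    solution — a point in the saturated parameter space from which EM ascent
    can only close the gap.
    """
    saturated = fit(X, Q, link=link, **fit_kwargs)
    restricted = fit(X, Q, link=link, hierarchy=hierarchy, **fit_kwargs)
    if saturated.loglik < restricted.loglik:
        space = restricted.space
        mask = permissible_mask(hierarchy, space)
        init_probs = []
        for j, (gmap_full, _) in enumerate(
                reduced_groups(Q[j], space) for j in range(Q.shape[0])):
            probs = np.array(saturated.item_probs[j], dtype=float)
            reach = np.unique(gmap_full[mask])
            probs[reach] = restricted.item_probs[j]
            init_probs.append(probs)
        eps = 1e-4
        init_pi = np.full(space.L, eps)
        init_pi[mask] += restricted.pi[mask] * (1.0 - eps * (~mask).sum())
        init_pi /= init_pi.sum()
        retry = fit(X, Q, link=link, init_item_probs=init_probs,
                    init_pi=init_pi, **fit_kwargs)
        if retry.loglik > saturated.loglik:
            saturated = retry
    return saturated, restricted
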