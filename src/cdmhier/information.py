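"""Score vectors, XPD and Obs information matrices, parameter covariance.

The free-parameter vector is gamma = (item group probabilities, free
structural probabilities pi_1 .. pi_{L-1}); the all-ones pattern is the
reference class, so a unit increase of a free pi is compensated by the
reference class.  Per-examinee scores have closed forms in the probability
parameterization:

* d l_i / d pi_m      = p_im / D_i - p_iL / D_i,
* d l_i / d P_jg      = [sum_{l in g} post_il] (x_ij - P_jg) / (P_jg (1 - P_jg)),

with p_il the class-conditional likelihood of row i and D_i its mixture over
classes.  The XPD information is the sum of outer products of these scores;
the Obs information is the negative Hessian of the observed-data
log-likelihood, computed here by central finite differences of the analytic
gradient (robust across restrictions, validated against closed forms in the
test suite).  Covariances come from a tolerance-based pseudo-inverse of the
information with the rank recorded; the structural block Sigma_pipi is the
lower-right (L-1) x (L-1) block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .em import ModelFit
from .model import pattern_loglik

__all__ = [
    "CovarianceEstimate",
    "score_contributions",
    "xpd_information",
    "obs_information",
    "covariance",
]

# conventional pseudo-inverse truncation: singular values below
# sqrt(machine epsilon) * s_max are treated as zero (the MASS::ginv default)
SV_RTOL = float(np.sqrt(np.finfo(float).eps))


@dataclass
class CovarianceEstimate:
    """Covariance of the free parameters from one information estimator."""

    estimator: str                  # "XPD" | "Obs"
    cov: np.ndarray                 # full free-parameter covariance
    sigma_pp: np.ndarray            # structural block, (L-1) x (L-1) saturated
    param_index: list
    rank: int
    rcond: float
    warnings_: list = field(default_factory=list)


def _unpack_gamma(fit: ModelFit, gamma: np.ndarray):
    """Split a gamma vector into per-item probability arrays and the
    structural vector over the fit's support (reference class imputed)."""
    item_probs = []
    ofs = 0
    for p in fit.item_probs:
        item_probs.append(np.asarray(gamma[ofs:ofs + len(p)], dtype=float))
        ofs += len(p)
    pi_free = np.asarray(gamma[ofs:], dtype=float)
    pi_support = np.empty(len(fit.support))
    pi_support[:-1] = pi_free
    pi_support[-1] = 1.0 - pi_free.sum()
    return item_probs, pi_support


def _group_indicators(fit: ModelFit) -> list:
    """Per item, the S x G indicator matrix mapping admitted classes to the
    item's reduced groups."""
    S = len(fit.support)
    out = []
    for j in range(fit.Q.shape[0]):
        G = len(fit.item_probs[j])
        memb = np.zeros((S, G))
        memb[np.arange(S), fit.group_maps[j]] = 1.0
        out.append(memb)
    return out


def _score_matrix(fit: ModelFit, X, gamma=None, indicators=None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if gamma is None:
        gamma = fit.gamma()
    if indicators is None:
        indicators = _group_indicators(fit)
    item_probs, pi_support = _unpack_gamma(fit, gamma)
    S = len(fit.support)
    J = fit.Q.shape[0]

    P = np.empty((J, S))
    for j in range(J):
        P[j] = item_probs[j][fit.group_maps[j]]
    logp = pattern_loglik(X, P)
    logw = logp + np.log(np.maximum(pi_support, 1e-300))
    logD = logsumexp(logw, axis=1, keepdims=True)
    ratio = np.exp(logp - logD)          # p_il / D_i, N x S
    post = np.exp(logw - logD)           # posterior memberships

    scores = np.empty((N, len(gamma)))
    ofs = 0
    for j in range(J):
        G = len(item_probs[j])
        postG = post @ indicators[j]     # N x G expected group membership
        p = item_probs[j]
        w = (X[:, [j]] - p[None, :]) / (p * (1.0 - p))[None, :]
        scores[:, ofs:ofs + G] = postG * w
        ofs += G
    scores[:, ofs:] = ratio[:, :-1] - ratio[:, [-1]]
    return scores


def _gradient(fit: ModelFit, X, gamma: np.ndarray) -> np.ndarray:
    """Total-gradient (column sums of the score matrix) without forming the
    N x dim score matrix: the item-parameter block reduces to expected group
    successes and memberships, the structural block to posterior ratios."""
    X = np.asarray(X, dtype=float)
    item_probs, pi_support = _unpack_gamma(fit, gamma)
    S = len(fit.support)
    J = fit.Q.shape[0]
    P = np.empty((J, S))
    for j in range(J):
        P[j] = item_probs[j][fit.group_maps[j]]
    logp = pattern_loglik(X, P)
    logw = logp + np.log(np.maximum(pi_support, 1e-300))
    logD = logsumexp(logw, axis=1, keepdims=True)
    ratio_sum = np.exp(logp - logD).sum(axis=0)      # sum_i p_il / D_i
    post = np.exp(logw - logD)
    n_bar = post.sum(axis=0)
    succ = post.T @ X                                # S x J expected successes

    grad = np.empty(len(gamma))
    ofs = 0
    for j in range(J):
        G = len(item_probs[j])
        memb = np.bincount(fit.group_maps[j], weights=n_bar, minlength=G)
        hits = np.bincount(fit.group_maps[j], weights=succ[:, j], minlength=G)
        p = item_probs[j]
        grad[ofs:ofs + G] = (hits - p * memb) / (p * (1.0 - p))
        ofs += G
    grad[ofs:] = ratio_sum[:-1] - ratio_sum[-1]
    return grad


def score_contributions(fit: ModelFit, X) -> np.ndarray:
    """Per-examinee score matrix (N x dim gamma) at the fitted parameters.

    Row i is the gradient of examinee i's log-likelihood contribution with
    respect to gamma; at an interior maximum the column sums vanish.
    """
    return _score_matrix(fit, X)


def xpd_information(scores: np.ndarray) -> np.ndarray:
    """Empirical cross-product information: sum_i s_i s_i' (symmetric PSD)."""
    scores = np.asarray(scores, dtype=float)
    info = scores.T @ scores
    return 0.5 * (info + info.T)


def obs_information(fit: ModelFit, X) -> np.ndarray:
    """Observed information: negative Hessian of the observed-data
    log-likelihood at the estimates, in closed form.

    Each examinee's mixture likelihood ``D_i = sum_l pi_l p_il`` is linear in
    every free parameter and multilinear overall (the Bernoulli factor
    ``P^x (1-P)^(1-x)`` is linear in P), so

        -d2 l_i / d a d b = s_ia s_ib - (d2 D_i / d a d b) / D_i,

    i.e. the observed information equals the XPD information minus a
    mixture-curvature correction C whose structural-structural block is zero
    (the Obs and XPD structural blocks coincide exactly).  The closed form
    stays valid at boundary-floored structural estimates, where
    finite-difference schemes would step outside the simplex.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    gamma = fit.gamma()
    dim = len(gamma)
    item_probs, pi_support = _unpack_gamma(fit, gamma)
    S = len(fit.support)
    J = fit.Q.shape[0]

    P = np.empty((J, S))
    for j in range(J):
        P[j] = item_probs[j][fit.group_maps[j]]
    logp = pattern_loglik(X, P)
    logw = logp + np.log(np.maximum(pi_support, 1e-300))
    logD = logsumexp(logw, axis=1, keepdims=True)
    ratio = np.exp(logp - logD)          # p_il / D_i
    post = np.exp(logw - logD)

    scores = _score_matrix(fit, X, gamma)
    info = scores.T @ scores             # XPD part

    # parameter offsets: offset[j] + group is the column of P_{j,group}
    offsets = np.cumsum([0] + [len(p) for p in item_probs])
    n_item = int(offsets[-1])

    # W[i, j, l-block]: Bernoulli weight of item j at class l's group,
    # evaluated column by column over classes
    C = np.zeros((dim, dim))
    Tpi = np.empty((S, J))               # sum_i ratio_il w_ij^{g_j(l)}
    for l in range(S):
        pj = P[:, l]                     # active group probability per item
        V = (X - pj[None, :]) / (pj * (1.0 - pj))[None, :]   # N x J
        Tpi[l] = ratio[:, l] @ V
        Cl = V.T @ (post[:, l][:, None] * V)                 # J x J
        np.fill_diagonal(Cl, 0.0)        # same-item curvature vanishes
        cols = offsets[:-1] + np.array([fit.group_maps[j][l] for j in range(J)])
        C[np.ix_(cols, cols)] += Cl

    # pi-item cross blocks: d2 D / d pi_m d P_jg with the all-ones reference
    # class compensating each free pi
    colsL = offsets[:-1] + np.array([fit.group_maps[j][S - 1] for j in range(J)])
    for m in range(S - 1):
        cols = offsets[:-1] + np.array([fit.group_maps[j][m] for j in range(J)])
        row = np.zeros(dim)
        np.add.at(row, cols, Tpi[m])
        np.add.at(row, colsL, -Tpi[S - 1])
        C[n_item + m, :] += row
        C[:, n_item + m] += row

    info -= C
    return 0.5 * (info + info.T)


PI_BOUNDARY_TOL = 1e-12  # structural estimates at most this are boundary zeros


def covariance(info: np.ndarray, estimator: str, fit: ModelFit) -> CovarianceEstimate:
    """Invert an information matrix into a free-parameter covariance.

    Structural parameters whose estimates sit on the boundary (probability
    effectively zero — below ``PI_BOUNDARY_TOL``) are treated as fixed: their
    rows and columns are removed before inversion and restored as zeros in
    the covariance.  Leaving them in would pollute the inverse through
    numerically null directions, and a boundary parameter has no meaningful
    Wald variance in any case.  The reduced matrix is inverted with a
    tolerance-based pseudo-inverse (singular values below ``1e-12 * s_max``
    treated as zero); rank deficiency and near-singularity are recorded on
    the result rather than raised.
    """
    info = np.asarray(info, dtype=float)
    dim = info.shape[0]
    n_item = fit.n_item_params
    pi_free = fit.pi[fit.support[:-1]]
    keep = np.concatenate([np.ones(n_item, dtype=bool), pi_free > PI_BOUNDARY_TOL])
    notes = []
    n_fixed = int((~keep).sum())
    if n_fixed:
        notes.append(f"{n_fixed} boundary structural parameter(s) fixed at zero")

    red = 0.5 * (info + info.T)[np.ix_(keep, keep)]
    U, s, Vt = np.linalg.svd(red)
    smax = s[0] if s.size else 0.0
    kept_sv = s > SV_RTOL * smax
    rank = int(kept_sv.sum())
    rcond = float(s[-1] / smax) if smax > 0 else 0.0
    inv_s = np.where(kept_sv, 1.0 / np.where(kept_sv, s, 1.0), 0.0)
    cov_red = (Vt.T * inv_s) @ U.T
    cov = np.zeros((dim, dim))
    cov[np.ix_(keep, keep)] = cov_red
    if rank < red.shape[0]:
        notes.append(f"information rank deficient: rank {rank} < dim {red.shape[0]}")
    if rcond < SV_RTOL:
        notes.append(f"information nearly singular (rcond {rcond:.2e})")
    ns = fit.n_struct_params
    return CovarianceEstimate(
        estimator=estimator, cov=cov, sigma_pp=cov[-ns:, -ns:],
        param_index=fit.param_index, rank=rank, rcond=rcond, warnings_=notes,
    )
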