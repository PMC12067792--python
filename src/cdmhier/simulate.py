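"""Synthetic data generation for the Type I error and power studies.

The generator reproduces the study conditions used throughout the package's
simulation harness:

* Q-matrix: J = 30 items over K attributes; the first 2K rows are two K x K
  identity blocks (securing identifiability), the remaining rows are drawn
  uniformly from the nonzero binary vectors and repaired so every attribute
  is measured by at least three items.
* Item quality: the probability of a correct response is ``P0`` for examinees
  mastering none of an item's required attributes and ``P1`` for examinees
  mastering all of them, with (P0, P1) = (0.1, 0.9), (0.2, 0.8), (0.3, 0.7)
  for high / moderate / low quality; every main and interaction effect on the
  probability scale equals ``(P1 - P0) / s_j`` with ``s_j = 2**K_j - 1`` the
  number of effects.
* Attributes: either uniform over the permissible patterns of the hierarchy
  being studied, or non-uniform via a dichotomized multivariate normal (mean
  zero, unit variances, off-diagonal correlations drawn once per dataset from
  U(0.5, 0.8), threshold zero), rejection-sampled to the permissible set when
  a hierarchy is active.  With an empty hierarchy all ``2**K`` patterns are
  reachable (the power regime).
* Responses: independent Bernoulli draws by the uniform-comparison rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hierarchy import AttributeHierarchy, permissible_mask
from .model import item_subsets, validate_qmatrix
from .patterns import enumerate_patterns

__all__ = [
    "ITEM_QUALITY",
    "SimDesign",
    "gen_qmatrix",
    "study_qmatrix",
    "gen_item_params",
    "gen_attributes",
    "gen_responses",
    "simulate_dataset",
]

ITEM_QUALITY = {"high": (0.1, 0.9), "moderate": (0.2, 0.8), "low": (0.3, 0.7)}


@dataclass(frozen=True)
class SimDesign:
    """One cell of the factorial simulation design."""

    N: int = 200
    K: int = 3
    J: int = 30
    quality: str = "high"
    hierarchy_name: str = "linear"
    distribution: str = "uniform"      # "uniform" | "non-uniform"
    replications: int = 500
    base_seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.quality not in ITEM_QUALITY:
            raise ValueError(f"unknown item quality {self.quality!r}")
        if self.distribution not in ("uniform", "non-uniform"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.replications < 0:
            raise ValueError("replications must be >= 0")


def gen_qmatrix(J: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random J x K Q-matrix with two leading identity blocks.

    Rows 1..K and K+1..2K are identity blocks; the remaining rows are uniform
    over nonzero binary vectors, then repaired so every attribute is measured
    by at least three items.
    """
    if J < 2 * K:
        raise ValueError(f"need J >= 2K for the two identity blocks (J={J}, K={K})")
    Q = np.zeros((J, K), dtype=np.int8)
    Q[:K] = np.eye(K, dtype=np.int8)
    Q[K:2 * K] = np.eye(K, dtype=np.int8)
    for j in range(2 * K, J):
        row = np.zeros(K, dtype=np.int8)
        while row.sum() == 0:
            row = rng.integers(0, 2, size=K).astype(np.int8)
        Q[j] = row
    # repair: each attribute measured >= 3 times (identity blocks give 2)
    for k in np.flatnonzero(Q.sum(axis=0) < 3):
        candidates = [j for j in range(2 * K, J) if Q[j, k] == 0]
        need = 3 - int(Q[:, k].sum())
        for j in rng.choice(candidates, size=need, replace=False):
            Q[j, k] = 1
    return validate_qmatrix(Q)


def study_qmatrix(J: int, K: int) -> np.ndarray:
    """The fixed J x K study Q-matrix: the deterministic centre of the random
    design used by :func:`gen_qmatrix`.

    The replication studies use one fixed test design (the Q-matrix is part
    of the condition, not redrawn per replication or per run).  Rows 1..2K
    are the two identity blocks; the remaining rows are allocated to
    complexity strata (number of required attributes) proportionally to how
    often each stratum arises under a uniform draw from the nonzero vectors
    — i.e. proportional to binomial(K, k) — with largest-remainder rounding,
    and within a stratum the q-vectors cycle in canonical pattern order.
    This pins the empirical rejection rates to a reproducible design whose
    composition matches the random design's expectation.
    """
    if J < 2 * K:
        raise ValueError(f"need J >= 2K for the two identity blocks (J={J}, K={K})")
    space = enumerate_patterns(K)
    nonzero = space.patterns[1:]                     # canonical order, no zero row
    weights = np.array([np.sum(nonzero.sum(axis=1) == k) for k in range(1, K + 1)])
    n_random = J - 2 * K
    quota = n_random * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    for idx in np.argsort(-(quota - counts))[: n_random - counts.sum()]:
        counts[idx] += 1
    rows = []
    for k, c in enumerate(counts, start=1):
        stratum = nonzero[nonzero.sum(axis=1) == k]
        for i in range(c):
            rows.append(stratum[i % len(stratum)])
    Q = np.vstack([np.eye(K, dtype=np.int8), np.eye(K, dtype=np.int8),
                   np.array(rows, dtype=np.int8)])
    return validate_qmatrix(Q)


def gen_item_params(Q, quality: str) -> list[np.ndarray]:
    """Identity-link item parameters per item: ``[P0, inc, inc, ...]`` with
    one equal increment ``(P1 - P0) / s_j`` per main/interaction effect."""
    Q = validate_qmatrix(Q)
    P0, P1 = ITEM_QUALITY[quality]
    params = []
    for q in Q:
        s_j = 2 ** int(q.sum()) - 1
        params.append(np.concatenate([[P0], np.full(s_j, (P1 - P0) / s_j)]))
    return params


def _correlation_matrix(K: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-diagonal matrix with off-diagonals ~ U(0.5, 0.8), repaired to the
    nearest positive definite matrix by eigenvalue clipping if needed."""
    C = np.eye(K)
    iu = np.triu_indices(K, k=1)
    vals = rng.uniform(0.5, 0.8, size=len(iu[0]))
    C[iu] = vals
    C.T[iu] = vals
    w, V = np.linalg.eigh(C)
    if w.min() <= 1e-8:
        w = np.clip(w, 1e-8, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


def gen_attributes(
    N: int,
    hierarchy: AttributeHierarchy,
    distribution: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw N attribute mastery patterns; returns 0-based canonical pattern
    positions.

    ``uniform``: i.i.d. uniform over the hierarchy's permissible patterns.
    ``non-uniform``: latent multivariate normal (mean 0, unit variance,
    correlations ~ U(0.5, 0.8) drawn once per call) dichotomized at zero;
    under an active hierarchy impermissible draws are rejected and redrawn.
    """
    space = enumerate_patterns(hierarchy.K)
    mask = permissible_mask(hierarchy, space)
    if distribution == "uniform":
        permissible = np.flatnonzero(mask)
        return rng.choice(permissible, size=N)
    if distribution != "non-uniform":
        raise ValueError(f"unknown distribution {distribution!r}")
    C = _correlation_matrix(hierarchy.K, rng)
    chol = np.linalg.cholesky(C)
    positions = np.empty(N, dtype=np.intp)
    filled = 0
    while filled < N:
        draw = max(N - filled, 16)
        Z = rng.standard_normal((draw, hierarchy.K)) @ chol.T
        pats = (Z > 0).astype(np.int8)
        pos = np.array([space.position(p) - 1 for p in pats], dtype=np.intp)
        ok = pos[mask[pos]]
        take = min(len(ok), N - filled)
        positions[filled:filled + take] = ok[:take]
        filled += take
    return positions


def response_prob_table(Q, item_params) -> np.ndarray:
    """J x L table of success probabilities from identity-link parameters
    (baseline plus the increments of every mastered effect subset)."""
    Q = validate_qmatrix(Q)
    space = enumerate_patterns(Q.shape[1])
    table = np.empty((Q.shape[0], space.L))
    for j, (q, delta) in enumerate(zip(Q, item_params)):
        req = np.flatnonzero(q == 1)
        subs = item_subsets(q)
        sub_masks = np.array(
            [[1 if (k + 1) in S else 0 for k in req] for S in subs], dtype=np.int8)
        gp = space.patterns[:, req]                         # L x K_j
        contains = (gp[:, None, :] >= sub_masks[None, :, :]).all(axis=2)
        p = delta[0] + contains @ np.asarray(delta[1:], dtype=float)
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError(f"item {j + 1}: identity-link probabilities leave [0, 1]")
        table[j] = np.clip(p, 0.0, 1.0)
    return table


def gen_responses(positions, Q, item_params, rng: np.random.Generator) -> np.ndarray:
    """Binary response matrix: each cell is 1 when the model probability for
    the examinee's pattern exceeds an independent U(0, 1) draw."""
    table = response_prob_table(Q, item_params)      # J x L
    probs = table[:, positions].T                    # N x J
    u = rng.random(probs.shape)
    return (probs > u).astype(np.int8)


def simulate_dataset(
    design: SimDesign,
    hierarchy: AttributeHierarchy,
    rng: np.random.Generator,
    generating_hierarchy: AttributeHierarchy | None = None,
    Q=None,
):
    """Generate one dataset for a design cell.

    ``generating_hierarchy`` defaults to ``hierarchy`` (the null regime, data
    honour the hierarchy); pass the empty hierarchy for the power regime.
    The Q-matrix is a fixed test design: pass ``Q`` to reuse one across
    replications (as the study harness does), or leave it None to draw one.
    Returns ``(X, Q, positions)``.
    """
    gen_h = hierarchy if generating_hierarchy is None else generating_hierarchy
    if Q is None:
        Q = gen_qmatrix(design.J, design.K, rng)
    positions = gen_attributes(design.N, gen_h, design.distribution, rng)
    X = gen_responses(positions, Q, gen_item_params(Q, design.quality), rng)
    return X, Q, positions
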