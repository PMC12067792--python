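"""Attribute hierarchies: prerequisite relations, permissible patterns, R.

An attribute hierarchy is a directed acyclic relation among the K latent
attributes in which an edge ``a -> b`` states that mastering attribute ``a``
is a prerequisite for mastering attribute ``b``.  A mastery pattern is
*permissible* under the hierarchy when every mastered attribute has all of its
prerequisites mastered; the remaining patterns are impermissible and their
structural probabilities are zero under the hierarchical model.

The constraint matrix ``R`` selects exactly the impermissible structural
parameters out of the free structural vector ``pi_1 .. pi_{L-1}`` (the
all-ones pattern, permissible under every hierarchy, serves as the reference
class completing the sum-to-one constraint), so that ``R @ pi_free`` is the
vector of probabilities the Wald test checks against zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import PatternSpace, enumerate_patterns

__all__ = [
    "AttributeHierarchy",
    "hierarchy_preset",
    "permissible_mask",
    "permissible_set",
    "constraint_matrix",
    "HIERARCHY_PRESETS",
]


@dataclass(frozen=True)
class AttributeHierarchy:
    """A prerequisite relation among ``K`` attributes.

    Parameters
    ----------
    K : int
        Number of attributes.
    prerequisites : frozenset[tuple[int, int]]
        Ordered pairs ``(a, b)`` (1-based) meaning attribute ``a`` must be
        mastered before attribute ``b``.  The empty relation is a valid
        "no hierarchy" specification.
    name : str
        Optional label (``linear``, ``pyramid``, ...).
    """

    K: int
    prerequisites: frozenset = field(default_factory=frozenset)
    name: str = "custom"

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        pairs = frozenset((int(a), int(b)) for a, b in self.prerequisites)
        object.__setattr__(self, "prerequisites", pairs)
        for a, b in pairs:
            if not (1 <= a <= self.K and 1 <= b <= self.K):
                raise ValueError(f"prerequisite ({a},{b}) outside attributes 1..{self.K}")
            if a == b:
                raise ValueError(f"self-loop ({a},{b}) not allowed")
        if self._has_cycle():
            raise ValueError("prerequisite relation contains a cycle")

    def _has_cycle(self) -> bool:
        succ: dict[int, set[int]] = {k: set() for k in range(1, self.K + 1)}
        for a, b in self.prerequisites:
            succ[a].add(b)
        WHITE, GREY, BLACK = 0, 1, 2
        color = {k: WHITE for k in succ}

        def visit(u: int) -> bool:
            color[u] = GREY
            for v in succ[u]:
                if color[v] == GREY or (color[v] == WHITE and visit(v)):
                    return True
            color[u] = BLACK
            return False

        return any(color[k] == WHITE and visit(k) for k in succ)

    @property
    def is_empty(self) -> bool:
        return len(self.prerequisites) == 0


# Prerequisite DAGs for the named hierarchy shapes, transcribed from the
# standard attribute-hierarchy taxonomy (linear chain; pyramid = divergent from
# a single apex; inverted pyramid = convergent to a single apex; diamond =
# narrow-wide-narrow).  Attribute 1 is the apex of the pyramid/diamond and the
# root of the linear chain.
HIERARCHY_PRESETS: dict[tuple[str, int], frozenset] = {
    ("linear", 3): frozenset({(1, 2), (2, 3)}),
    ("pyramid", 3): frozenset({(1, 2), (1, 3)}),
    ("inverted_pyramid", 3): frozenset({(1, 3), (2, 3)}),
    ("linear", 5): frozenset({(1, 2), (2, 3), (3, 4), (4, 5)}),
    ("pyramid", 5): frozenset({(1, 2), (1, 3), (2, 4), (3, 5)}),
    ("inverted_pyramid", 5): frozenset({(1, 3), (2, 4), (3, 5), (4, 5)}),
    ("diamond", 5): frozenset({(1, 2), (1, 3), (1, 4), (2, 5), (3, 5), (4, 5)}),
}


def hierarchy_preset(name: str, K: int) -> AttributeHierarchy:
    """Build one of the named hierarchies (``linear``, ``pyramid``,
    ``inverted_pyramid`` for K=3 and K=5; ``diamond`` for K=5; ``none`` for
    the empty relation at any K)."""
    if name in ("none", "empty"):
        return AttributeHierarchy(K=K, prerequisites=frozenset(), name="none")
    if name == "linear":  # the chain generalizes to any K
        pairs = frozenset((k, k + 1) for k in range(1, K))
        return AttributeHierarchy(K=K, prerequisites=pairs, name="linear")
    key = (name, K)
    if key not in HIERARCHY_PRESETS:
        known = sorted({n for n, k in HIERARCHY_PRESETS} | {"none"})
        raise KeyError(f"no preset {name!r} for K={K}; known presets: {known}")
    return AttributeHierarchy(K=K, prerequisites=HIERARCHY_PRESETS[key], name=name)


def permissible_mask(h: AttributeHierarchy, space: PatternSpace | None = None) -> np.ndarray:
    """Boolean mask over canonical pattern positions, True where permissible.

    A pattern is permissible iff for every prerequisite pair ``(a, b)``,
    mastery of ``b`` implies mastery of ``a``.
    """
    if space is None:
        space = enumerate_patterns(h.K)
    if space.K != h.K:
        raise ValueError("pattern space and hierarchy disagree on K")
    mask = np.ones(space.L, dtype=bool)
    pats = space.patterns
    for a, b in h.prerequisites:
        mask &= ~((pats[:, b - 1] == 1) & (pats[:, a - 1] == 0))
    return mask


def permissible_set(h: AttributeHierarchy, space: PatternSpace | None = None) -> list[int]:
    """1-based canonical positions of the permissible patterns, ascending."""
    if space is None:
        space = enumerate_patterns(h.K)
    return [int(l) + 1 for l in np.flatnonzero(permissible_mask(h, space))]


def constraint_matrix(h: AttributeHierarchy, space: PatternSpace | None = None) -> np.ndarray:
    """Selector matrix ``R`` for the Wald test of an attribute hierarchy.

    ``R`` has one row per impermissible pattern and ``L - 1`` columns (the
    free structural parameters ``pi_1 .. pi_{L-1}``); row ``i`` holds a single
    1 in the column of the i-th impermissible position, ascending, so that
    ``R @ pi_free`` stacks the impermissible-pattern probabilities.

    Raises
    ------
    ValueError
        If the hierarchy admits every pattern (nothing to test).
    """
    if space is None:
        space = enumerate_patterns(h.K)
    mask = permissible_mask(h, space)
    imperm = np.flatnonzero(~mask)  # 0-based positions
    if imperm.size == 0:
        raise ValueError("hierarchy has no impermissible pattern: nothing to test")
    # the all-ones reference class (last position) is always permissible, so
    # every impermissible position indexes a free parameter
    R = np.zeros((imperm.size, space.L - 1))
    R[np.arange(imperm.size), imperm] = 1.0
    return R
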