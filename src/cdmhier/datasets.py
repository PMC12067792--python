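"""The ECPE grammar-section example.

The Examination for the Certificate of Proficiency in English (ECPE) grammar
section is the standard real-data example for attribute-hierarchy testing:
28 items measuring three attributes — (1) morphosyntactic rules, (2) cohesive
rules, (3) lexical rules — answered by 2,922 examinees, with a much-studied
linear hierarchy in which lexical rules are prerequisite to cohesive rules
and cohesive rules to morphosyntactic rules (3 -> 2 -> 1).

The Q-matrix below is the published 28 x 3 design and is embedded here.  The
item response data are distributed with the CDM R package
(https://CRAN.R-project.org/package=CDM, ``data(data.ecpe)``) and are not
redistributed; export them to CSV (items only, or with a leading id column)
and pass the path to :func:`load_ecpe`.
"""

from __future__ import annotations

import numpy as np

from .hierarchy import AttributeHierarchy
from .io import read_responses

__all__ = ["ecpe_qmatrix", "ecpe_linear_hierarchy", "load_ecpe"]

# attributes: morphosyntactic, cohesive, lexical
_ECPE_Q = [
    (1, 1, 0), (0, 1, 0), (1, 0, 1), (0, 0, 1), (0, 0, 1), (0, 0, 1), (1, 0, 1),
    (0, 1, 0), (0, 0, 1), (1, 0, 0), (1, 0, 1), (1, 0, 1), (1, 0, 0), (1, 0, 0),
    (0, 0, 1), (1, 0, 1), (0, 1, 1), (0, 0, 1), (0, 0, 1), (1, 0, 1), (1, 0, 1),
    (0, 0, 1), (0, 1, 0), (0, 1, 0), (1, 0, 0), (0, 0, 1), (1, 0, 0), (0, 0, 1),
]


def ecpe_qmatrix() -> np.ndarray:
    """The published 28 x 3 ECPE Q-matrix."""
    return np.array(_ECPE_Q, dtype=np.int8)


def ecpe_linear_hierarchy() -> AttributeHierarchy:
    """The linear hierarchy lexical -> cohesive -> morphosyntactic
    (attribute 3 prerequisite to 2, 2 prerequisite to 1)."""
    return AttributeHierarchy(K=3, prerequisites=frozenset({(3, 2), (2, 1)}),
                              name="linear")


def load_ecpe(path) -> tuple[np.ndarray, np.ndarray]:
    """Load user-supplied ECPE responses (CSV) and pair them with the
    embedded Q-matrix; returns ``(X, Q)``."""
    X = read_responses(path)
    Q = ecpe_qmatrix()
    if X.shape[1] != Q.shape[0]:
        raise ValueError(
            f"expected {Q.shape[0]} item columns, got {X.shape[1]}")
    return X, Q
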