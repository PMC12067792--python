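"""Attribute mastery pattern space.

An attribute mastery pattern is a binary vector ``alpha`` of length K whose
k-th entry records whether the examinee has mastered attribute k.  Without
structural constraints there are ``L = 2**K`` patterns.  All of the package's
positional conventions (structural parameter indices, constraint-matrix
columns, reduced latent groups) refer to the canonical ordering implemented
here: patterns are sorted by the number of mastered attributes, and within a
mastery count by descending value of the pattern read as a binary number with
attribute 1 as the most significant bit.  For K = 3 this gives

    000, 100, 010, 001, 110, 101, 011, 111

so that, e.g., position 3 is (0,1,0) and position 6 is (1,0,1).  Positions are
1-based in user-facing APIs (matching the pi_l subscripts used in the
cognitive-diagnosis literature) and 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PatternSpace", "enumerate_patterns"]


def _canonical_order_key(bits: tuple[int, ...]) -> tuple[int, int]:
    value = int("".join(str(b) for b in bits), 2)  # attribute 1 = MSB
    return (sum(bits), -value)


@dataclass(frozen=True)
class PatternSpace:
    """All ``2**K`` mastery patterns in canonical order.

    Attributes
    ----------
    K : int
        Number of attributes.
    patterns : np.ndarray
        ``(2**K, K)`` binary array; row ``l`` is the pattern at 0-based
        position ``l``.
    """

    K: int
    patterns: np.ndarray
    _index: dict = field(repr=False, default_factory=dict)

    @property
    def L(self) -> int:
        return 2 ** self.K

    def position(self, pattern) -> int:
        """1-based position of a pattern."""
        key = tuple(int(b) for b in pattern)
        if key not in self._index:
            raise KeyError(f"not a length-{self.K} binary pattern: {pattern}")
        return self._index[key] + 1

    def pattern(self, position: int) -> np.ndarray:
        """Pattern at a 1-based position."""
        if not 1 <= position <= self.L:
            raise IndexError(f"position {position} outside 1..{self.L}")
        return self.patterns[position - 1]

    def __len__(self) -> int:
        return self.L


def enumerate_patterns(K: int) -> PatternSpace:
    """Enumerate all ``2**K`` mastery patterns in canonical order.

    Position 1 is the all-zeros pattern and position ``2**K`` the all-ones
    pattern; intermediate patterns are ordered by mastery count, then by
    descending binary value (attribute 1 most significant).
    """
    if not isinstance(K, (int, np.integer)) or K < 1:
        raise ValueError(f"K must be a positive integer, got {K!r}")
    all_bits = sorted(
        (tuple(int(b) for b in np.binary_repr(v, width=K)) for v in range(2 ** K)),
        key=_canonical_order_key,
    )
    patterns = np.array(all_bits, dtype=np.int8)
    index = {bits: l for l, bits in enumerate(all_bits)}
    return PatternSpace(K=int(K), patterns=patterns, _index=index)
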