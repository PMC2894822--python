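"""Residue pairing: an ordered, crossing-free structural alignment.

Indices are 1-based sequential Cα indices (see :mod:`symscan.trace`).
A pairing is sequentially consistent: strictly increasing in both the
first-structure and second-structure index, and no residue used twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PreconditionError


@dataclass(frozen=True)
class ResiduePairing:
    """Aligned residue pairs (i in structure A, j in structure B)."""

    i: np.ndarray
    j: np.ndarray

    def __post_init__(self):
        i = np.asarray(self.i, dtype=np.int64)
        j = np.asarray(self.j, dtype=np.int64)
        if i.shape != j.shape or i.ndim != 1:
            raise PreconditionError("pairing index arrays must be equal-length 1-D")
        if len(i) > 1 and (np.any(np.diff(i) <= 0) or np.any(np.diff(j) <= 0)):
            raise PreconditionError(
                "pairing must be strictly increasing in both indices (no crossings)"
            )
        if len(i) and (i.min() < 1 or j.min() < 1):
            raise PreconditionError("pairing indices are 1-based")
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "j", j)

    def __len__(self) -> int:
        return len(self.i)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResiduePairing):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.array_equal(self.i, other.i))
            and bool(np.array_equal(self.j, other.j))
        )

    @classmethod
    def empty(cls) -> "ResiduePairing":
        return cls(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))

    @classmethod
    def from_pairs(cls, pairs) -> "ResiduePairing":
        if len(pairs) == 0:
            return cls.empty()
        arr = np.asarray(pairs, dtype=np.int64)
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def identity(cls, n: int) -> "ResiduePairing":
        idx = np.arange(1, n + 1)
        return cls(idx, idx.copy())

    def separations(self) -> np.ndarray:
        """|i - j| sequential separations, one per pair."""
        return np.abs(self.i - self.j)


def average_shift(pairing: ResiduePairing) -> float:
    """Mean sequential-index difference (i - j) over aligned pairs.

    Proxies the repeat length of open (helical) structures; for circular
    alignments of closed structures that straddle the wrap point the raw
    difference is reported as-is.
    """
    if len(pairing) == 0:
        raise PreconditionError("average_shift of an empty pairing")
    return float(np.mean(pairing.i - pairing.j))
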