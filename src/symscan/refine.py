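"""T-score and RSE refinement (superpose / realign iteration).

The T-score is a weighted count of aligned residues,

    T = sum over aligned pairs (i, j) of  1 / (1 + (d_ij / d0)^2),

with d0 = 2.0 Å, where d_ij is the Cα-Cα distance after the current
superposition, and pairs whose sequential separation |i - j| is s or
fewer residues (s = 3) contribute nothing — this suppresses the trivial
self-alignment, which would otherwise dominate every scan.

RSE refinement alternates two steps from an initial pairing: (1) Kabsch
superposition on the current pairing, (2) realignment of the superposed
structures. It stops at an alignment fixed point or after a set number
of cycles, and reports the cycle with the best T-score — which also
makes period-2 alignment oscillations harmless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sealign
from .errors import PreconditionError
from .geometry import RigidTransform, kabsch_superpose
from .pairing import ResiduePairing


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the scan, with field-standard defaults.

    d0
        Distance scale of the scoring kernel, Å. The kernel halves at d0.
    min_separation
        s: aligned pairs with |i - j| <= s are excluded from the T-score.
    max_iterations
        Cap on superpose/realign cycles per shift.
    axis_cosine_cutoff
        Two axes with |cos| below this are "different" (noise labelling).
    seed_cutoff, extend_cutoff, min_seed_len, backend
        Alignment parameters, see :mod:`symscan.sealign`.
    """

    d0: float = 2.0
    min_separation: int = 3
    max_iterations: int = 20
    axis_cosine_cutoff: float = 0.95
    seed_cutoff: float = sealign.DEFAULT_SEED_CUTOFF
    extend_cutoff: float = sealign.DEFAULT_EXTEND_CUTOFF
    min_seed_len: int = sealign.DEFAULT_MIN_SEED_LEN
    backend: str = "seed-extend"

    def __post_init__(self):
        if self.d0 <= 0:
            raise PreconditionError("d0 must be positive")
        if self.min_separation < 0:
            raise PreconditionError("min_separation must be >= 0")
        if self.max_iterations < 1:
            raise PreconditionError("max_iterations must be >= 1")
        if abs(self.axis_cosine_cutoff) > 1:
            raise PreconditionError("axis_cosine_cutoff must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "d0": self.d0,
            "min_separation": self.min_separation,
            "max_iterations": self.max_iterations,
            "axis_cosine_cutoff": self.axis_cosine_cutoff,
            "seed_cutoff": self.seed_cutoff,
            "extend_cutoff": self.extend_cutoff,
            "min_seed_len": self.min_seed_len,
            "backend": self.backend,
        }


def t_score(
    pairs: ResiduePairing,
    trace_a,
    trace_b,
    transform: RigidTransform,
    cfg: ScanConfig | None = None,
    j_original: np.ndarray | None = None,
) -> float:
    """Weighted aligned-residue count under the current superposition.

    Pairs with sequential separation |i - j| <= s contribute zero; an
    all-near-diagonal pairing therefore scores 0 regardless of geometry.

    ``j_original`` maps positions of structure B to original 1-based
    sequential indices. The alignment scan passes the circular
    permutation here so the separation rule always sees original
    indices; by default positions are their own indices.
    """
    cfg = cfg or ScanConfig()
    if len(pairs) == 0:
        return 0.0
    xa = getattr(trace_a, "coords", trace_a)
    xb = getattr(trace_b, "coords", trace_b)
    j_orig = pairs.j if j_original is None else j_original[pairs.j - 1]
    keep = np.abs(pairs.i - j_orig) > cfg.min_separation
    if not np.any(keep):
        return 0.0
    a = xa[pairs.i[keep] - 1]
    b = transform.apply(xb[pairs.j[keep] - 1])
    d2 = np.sum((a - b) ** 2, axis=1)
    return float(np.sum(1.0 / (1.0 + d2 / cfg.d0**2)))


def rse_refine(
    initial: ResiduePairing,
    trace_a,
    trace_b,
    cfg: ScanConfig | None = None,
    j_original: np.ndarray | None = None,
) -> tuple[ResiduePairing, RigidTransform, float, int]:
    """Refine an initial pairing by superpose/realign cycles.

    Returns ``(pairing, transform, t, n_cycles)`` for the cycle with the
    best T-score among all cycles actually visited. If realignment drops
    below 3 pairs mid-refinement, the best so far is returned.
    ``j_original`` is forwarded to the T-score (see :func:`t_score`).
    """
    cfg = cfg or ScanConfig()
    if len(initial) < 3:
        raise PreconditionError("refinement needs an initial pairing of >= 3 pairs")
    xa = np.asarray(getattr(trace_a, "coords", trace_a), dtype=float)
    xb = np.asarray(getattr(trace_b, "coords", trace_b), dtype=float)

    pairing = initial
    best: tuple[ResiduePairing, RigidTransform, float] | None = None
    n_cycles = 0
    for _ in range(cfg.max_iterations):
        n_cycles += 1
        transform, _rmsd = kabsch_superpose(pairing, xa, xb)
        t = t_score(pairing, xa, xb, transform, cfg, j_original=j_original)
        if best is None or t > best[2]:
            best = (pairing, transform, t)
        new_pairing = sealign.se_align(
            xa,
            transform.apply(xb),
            d0=cfg.d0,
            seed_cutoff=cfg.seed_cutoff,
            extend_cutoff=cfg.extend_cutoff,
            min_seed_len=cfg.min_seed_len,
            backend=cfg.backend,
        )
        if new_pairing == pairing or len(new_pairing) < 3:
            break
        pairing = new_pairing
    assert best is not None
    return best[0], best[1], best[2], n_cycles
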