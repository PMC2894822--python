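"""Gap-penalty-free structure-based sequence alignment of superposed traces.

Given two Cα traces already placed in a common frame, produce the
sequentially consistent set of residue pairs that the superposition
supports. The algorithm follows the seed / extend / select pattern:

1. *Seeds* — maximal runs of at least ``min_seed_len`` consecutive pairs
   (i, j) on one alignment diagonal (constant offset i - j) whose
   Cα-Cα distances are all below ``seed_cutoff``.
2. *Extension* — each seed grows residue-by-residue in both directions
   along its diagonal while the per-pair distance stays below
   ``extend_cutoff``.
3. *Selection* — extended seeds are admitted greedily in order of
   decreasing total kernel weight (sum of 1 / (1 + (d/d0)^2) over their
   pairs); pairs that would cross or reuse residues already claimed by a
   heavier segment are trimmed away.

There is no gap penalty anywhere: unaligned loops cost nothing, which is
what lets symmetric structures with variable-length insertions between
repeats still align unit-to-unit.

A dynamic-programming backend (``backend="dp"``) maximizes the same
kernel sum minus the kernel value at the extension cutoff (so pairs
beyond the cutoff are never profitable) with free gaps; it serves as an
independent cross-check on clean inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .pairing import ResiduePairing

DEFAULT_SEED_CUTOFF = 3.5  # Å; kernel ~ 0.25 here with d0 = 2
DEFAULT_EXTEND_CUTOFF = 6.0  # Å; kernel ~ 0.1
DEFAULT_MIN_SEED_LEN = 3


def _kernel(d: np.ndarray, d0: float) -> np.ndarray:
    return 1.0 / (1.0 + (d / d0) ** 2)


def _diagonal_segments(dist, seed_mask, ext_mask, min_seed_len):
    """Extended seed segments as (offset, j_start, j_end) half-open in j.

    Works diagonal-by-diagonal but only on diagonals that contain at
    least one seed-quality pair, which keeps the scan fast when the
    superposition is noise.
    """
    n_a, n_b = dist.shape
    rows, cols = np.nonzero(seed_mask)
    segments = []
    for off in np.unique(rows - cols):
        j_lo, j_hi = max(0, -off), min(n_b, n_a - off)
        seed_diag = seed_mask[np.arange(j_lo, j_hi) + off, np.arange(j_lo, j_hi)]
        # maximal runs of consecutive True
        padded = np.concatenate(([False], seed_diag, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        keep = (ends - starts) >= min_seed_len
        if not np.any(keep):
            continue
        ext_diag = ext_mask[np.arange(j_lo, j_hi) + off, np.arange(j_lo, j_hi)]
        merged: list[list[int]] = []
        for s, e in zip(starts[keep], ends[keep]):
            # grow within ext_mask in both directions along the diagonal
            while s > 0 and ext_diag[s - 1]:
                s -= 1
            while e < len(ext_diag) and ext_diag[e]:
                e += 1
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        segments.extend((off, j_lo + s, j_lo + e) for s, e in merged)
    return segments


def _select_consistent(segments, weights_fn):
    """Greedy weight-ordered admission with trimming of conflicting pairs.

    Maintains the chosen pairs as a strictly monotone mapping; a
    candidate pair survives iff inserting it keeps both index sequences
    strictly increasing.
    """
    scored = []
    for seg in segments:
        w, ii, jj = weights_fn(seg)
        scored.append((w, ii, jj))
    scored.sort(key=lambda x: -x[0])

    chosen_i: list[int] = []  # kept sorted
    chosen_j: list[int] = []
    import bisect

    for _, ii, jj in scored:
        for i, j in zip(ii, jj):
            pos = bisect.bisect_left(chosen_i, i)
            if pos < len(chosen_i) and chosen_i[pos] == i:
                continue  # residue i already used
            prev_ok = pos == 0 or chosen_j[pos - 1] < j
            next_ok = pos == len(chosen_i) or chosen_j[pos] > j
            if prev_ok and next_ok:
                chosen_i.insert(pos, i)
                chosen_j.insert(pos, j)
    if not chosen_i:
        return ResiduePairing.empty()
    return ResiduePairing(np.array(chosen_i) + 1, np.array(chosen_j) + 1)


def se_align(
    coords_a: np.ndarray,
    coords_b_transformed: np.ndarray,
    d0: float = 2.0,
    seed_cutoff: float = DEFAULT_SEED_CUTOFF,
    extend_cutoff: float = DEFAULT_EXTEND_CUTOFF,
    min_seed_len: int = DEFAULT_MIN_SEED_LEN,
    backend: str = "seed-extend",
) -> ResiduePairing:
    """Align two superposed Cα coordinate sets; returns 1-based pairs.

    ``coords_b_transformed`` must already carry the current rigid
    transform. An empty pairing (no seeds) is a legal result.
    """
    xa = np.asarray(getattr(coords_a, "coords", coords_a), dtype=float)
    xb = np.asarray(
        getattr(coords_b_transformed, "coords", coords_b_transformed), dtype=float
    )
    dist = cdist(xa, xb)
    if backend == "dp":
        return _dp_align(dist, d0, extend_cutoff)
    if backend != "seed-extend":
        raise ValueError(f"unknown alignment backend {backend!r}")

    seed_mask = dist < seed_cutoff
    if not seed_mask.any():
        return ResiduePairing.empty()
    ext_mask = dist < extend_cutoff
    segments = _diagonal_segments(dist, seed_mask, ext_mask, min_seed_len)

    kern = _kernel(dist, d0)

    def weights(seg):
        off, j0, j1 = seg
        jj = np.arange(j0, j1)
        ii = jj + off
        return float(kern[ii, jj].sum()), ii, jj

    return _select_consistent(segments, weights)


def _dp_align(dist: np.ndarray, d0: float, extend_cutoff: float) -> ResiduePairing:
    """No-gap-penalty global alignment maximizing the shifted kernel sum.

    Pair score = kernel(d) - kernel(extend_cutoff), so pairs farther than
    the extension cutoff are net losses and are skipped for free.
    """
    n_a, n_b = dist.shape
    score = _kernel(dist, d0) - _kernel(np.array(extend_cutoff), d0)
    F = np.zeros((n_a + 1, n_b + 1))
    # 0 = skip-a, 1 = skip-b, 2 = pair
    move = np.zeros((n_a + 1, n_b + 1), dtype=np.int8)
    for i in range(1, n_a + 1):
        fprev = F[i - 1]
        frow = F[i]
        diag = fprev[:-1] + score[i - 1]
        for jm1 in range(n_b):
            best = fprev[jm1 + 1]
            mv = 0
            if frow[jm1] > best:
                best = frow[jm1]
                mv = 1
            if diag[jm1] > best:
                best = diag[jm1]
                mv = 2
            frow[jm1 + 1] = best
            move[i, jm1 + 1] = mv
    ii, jj = [], []
    i, j = n_a, n_b
    while i > 0 and j > 0:
        mv = move[i, j]
        if mv == 2:
            ii.append(i)
            jj.append(j)
            i -= 1
            j -= 1
        elif mv == 1:
            j -= 1
        else:
            i -= 1
    if not ii:
        return ResiduePairing.empty()
    return ResiduePairing(np.array(ii[::-1]), np.array(jj[::-1]))
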