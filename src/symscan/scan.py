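"""The alignment scan: all N-3 circularly shifted self-alignments.

A structure A is compared with its own duplicate B. The k-th initial
alignment pairs residue i of B with residue i + k of A (no wraparound:
residues pushed past the C-terminus start unaligned), seeding the
refinement at every circular shift k = 1 .. N-3. For a structure with
n-fold rotational symmetry, the shift equal to one repeat length
realigns the whole structure onto itself, so the self-comparison scores
a full-length match instead of the (n-1)/n fraction a plain repeat
search would find — the scan amplifies the symmetry signal.

Internally each shift works on a circularly permuted copy of the
coordinate array: in the permuted index space a wrapped-around
alignment of a closed structure is sequentially monotone, which is what
lets the refinement recover the full-length circular match. The
separation rule (|i - j| > s) and the average alignment shift always
use the *original* sequential indices of both copies.

Each refined alignment keeps its T-score, optimal transform, screw-axis
decomposition and average alignment shift. The record with the highest
T-score is the 'best' alignment; records whose rotation axis differs
from the best one (axis cosine < cutoff) and that align no residue near
the diagonal are 'noise' — the null population used for Z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import PreconditionError, SymscanError
from .geometry import RigidTransform, ScrewAxis, axis_cosine, decompose_transform
from .pairing import ResiduePairing
from .refine import ScanConfig, rse_refine
from .trace import CaTrace


def initial_pairing(n: int, k: int) -> ResiduePairing:
    """Initial alignment at circular shift k: residue i of B with i + k of A.

    Residues for which i + k exceeds N are left unaligned (no
    wraparound), so the pairing has N - k pairs, in original indices.
    Any shift 1 <= k <= N - 1 yields a well-formed pairing; the scan
    itself stops at k = N - 3, where the initial alignment still has the
    3 pairs a superposition needs.
    """
    if not 1 <= k <= n - 1:
        raise PreconditionError(f"shift k={k} outside 1..N-1 for N={n}")
    j = np.arange(1, n - k + 1)
    return ResiduePairing(j + k, j)


def permuted_indices(n: int, k: int) -> np.ndarray:
    """Original 1-based residue index at each position of the k-permuted copy.

    Position p of the permuted copy holds residue ((p - 1 - k) mod N) + 1,
    so positions k+1 .. N hold residues 1 .. N-k (the initial diagonal)
    and positions 1 .. k hold the wrapped C-terminal residues.
    """
    return (np.arange(n) - k) % n + 1


@dataclass(frozen=True)
class ScanRecord:
    """One refined self-alignment at circular shift k.

    ``pairing`` lives in the permuted index space of the copy (where it
    is sequentially monotone); ``original_j`` gives the matching
    original 1-based indices of the copy, pair for pair.
    """

    shift: int
    pairing: ResiduePairing
    original_j: np.ndarray
    transform: RigidTransform | None
    axis: ScrewAxis | None
    t_score: float
    average_shift: float
    n_aligned: int
    z_score: float | None = None
    is_noise: bool | None = None

    @property
    def failed(self) -> bool:
        return self.transform is None

    def original_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(i in A, j in B) in original sequential indices, ordered by i."""
        return self.pairing.i, self.original_j

    def separations(self) -> np.ndarray:
        """|i - j| in original indices, one value per aligned pair."""
        return np.abs(self.pairing.i - self.original_j)


@dataclass(frozen=True)
class ScanResult:
    """All N-3 scan records for one trace, plus the best-record index."""

    records: tuple[ScanRecord, ...]
    best_index: int
    label: str
    n_residues: int
    config: ScanConfig

    @property
    def best(self) -> ScanRecord:
        return self.records[self.best_index]

    def noise_records(self) -> list[ScanRecord]:
        return [r for r in self.records if r.is_noise]


def _empty_record(k: int) -> ScanRecord:
    return ScanRecord(
        k, ResiduePairing.empty(), np.empty(0, dtype=np.int64),
        None, None, 0.0, float(k), 0,
    )


def alignment_scan(trace: CaTrace, cfg: ScanConfig | None = None) -> ScanResult:
    """Run the full self-alignment scan on one Cα trace.

    Deterministic: no randomness anywhere, so two runs on the same trace
    and config are bit-identical. A shift whose refinement fails yields
    an empty record with T = 0 rather than aborting the scan.
    """
    cfg = cfg or ScanConfig()
    n = len(trace)
    xa = trace.coords
    centroid = xa.mean(axis=0)

    raw: list[ScanRecord] = []
    for k in range(1, n - 2):
        jorig = permuted_indices(n, k)
        xb_perm = xa[jorig - 1]
        # initial alignment: the permuted-space diagonal p = k+1 .. N,
        # i.e. residue i of B with residue i + k of A, wrap unaligned
        diag = np.arange(k + 1, n + 1)
        init = ResiduePairing(diag, diag.copy())
        try:
            pairing, transform, t, _ = rse_refine(
                init, xa, xb_perm, cfg, j_original=jorig
            )
        except SymscanError:
            raw.append(_empty_record(k))
            continue
        orig_j = jorig[pairing.j - 1]
        avg_shift = (
            float(np.mean(pairing.i - orig_j)) if len(pairing) else float(k)
        )
        raw.append(
            ScanRecord(
                k,
                pairing,
                orig_j,
                transform,
                None,  # axis filled in once the best record is known
                t,
                avg_shift,
                len(pairing),
            )
        )

    best_index = int(np.argmax([r.t_score for r in raw]))

    # canonicalize all axis signs against the best alignment's axis so
    # that angles across the scan share one sign convention
    ref_dir = None
    if raw[best_index].transform is not None:
        ref_dir = decompose_transform(
            raw[best_index].transform, reference_point=centroid
        ).direction
    records = []
    for rec in raw:
        if rec.transform is None:
            records.append(rec)
            continue
        axis = decompose_transform(
            rec.transform, reference_axis=ref_dir, reference_point=centroid
        )
        records.append(replace(rec, axis=axis))

    return ScanResult(tuple(records), best_index, trace.label, n, cfg)


def label_noise(result: ScanResult, cfg: ScanConfig | None = None) -> ScanResult:
    """Mark the noise records: axis off the best's AND nothing near-diagonal.

    A record is noise exactly when (1) the cosine between its rotation
    axis and the best record's axis is below the cutoff and (2) every
    aligned pair satisfies |i - j| > s in original indices. The best
    record itself is never noise.
    """
    cfg = cfg or result.config
    best = result.best
    if best.axis is None:
        raise PreconditionError("best record has no axis; scan failed everywhere")
    labelled = []
    for idx, rec in enumerate(result.records):
        if idx == result.best_index or rec.axis is None:
            labelled.append(replace(rec, is_noise=False))
            continue
        off_axis = axis_cosine(rec.axis, best.axis) < cfg.axis_cosine_cutoff
        clear_of_diagonal = bool(
            len(rec.pairing) > 0
            and np.all(rec.separations() > cfg.min_separation)
        )
        labelled.append(replace(rec, is_noise=off_axis and clear_of_diagonal))
    return replace(result, records=tuple(labelled))


def group_by_axis(
    result: ScanResult,
    z_floor: float,
    angle_window_deg: float = 15.0,
    cosine_cutoff: float = 0.95,
) -> list[list[ScanRecord]]:
    """Cluster high-Z records by shared axis and rotation angle.

    Records with Z >= z_floor are grouped greedily: a record joins the
    first group whose top member has axis cosine >= ``cosine_cutoff``
    with it and a reported angle within ``angle_window_deg`` (circular
    distance). Members sort by Z descending within a group; groups sort
    by their smallest average alignment shift. For an n-fold symmetric
    structure the group angles land at multiples of 360/n.
    """
    eligible = [
        r
        for r in result.records
        if r.z_score is not None and r.z_score >= z_floor and r.axis is not None
    ]
    eligible.sort(key=lambda r: -r.z_score)
    groups: list[list[ScanRecord]] = []
    for rec in eligible:
        placed = False
        for grp in groups:
            top = grp[0]
            dang = abs(rec.axis.angle_deg - top.axis.angle_deg) % 360.0
            dang = min(dang, 360.0 - dang)
            if (
                axis_cosine(rec.axis, top.axis) >= cosine_cutoff
                and dang <= angle_window_deg
            ):
                grp.append(rec)
                placed = True
                break
        if not placed:
            groups.append([rec])
    groups.sort(key=lambda grp: min(r.average_shift for r in grp))
    return groups
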