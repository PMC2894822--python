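"""Human-readable symmetry reports and repeat-unit derivation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import NoiseModel, classify_symmetric, z_score
from .errors import PreconditionError
from .scan import ScanResult, group_by_axis

PERMISSIVE_Z = 8.0
STRICT_Z = 10.0


def derive_repeat_units(
    pairs_i: np.ndarray, pairs_j: np.ndarray, n: int
) -> list[tuple[int, int]]:
    """Residue ranges of the repeating units implied by the best alignment.

    The alignment maps residue j onto residue i = f(j): applying the
    symmetry operation advances the sequence by one repeating unit.
    Starting from the smallest aligned index, following f until the
    index leaves the chain (or wraps back) visits each unit boundary
    once; the gaps between visits are the unit ranges.

    Raises if more than half the chain is unaligned (units undetermined).
    """
    if len(pairs_i) == 0:
        raise PreconditionError("empty pairing: repeat units undetermined")
    if len(pairs_i) < n / 2:
        raise PreconditionError(
            f"only {len(pairs_i)}/{n} residues aligned (>50% unaligned): "
            "repeat units undetermined"
        )
    j_sorted = np.asarray(pairs_j)
    order = np.argsort(j_sorted)
    j_sorted = j_sorted[order]
    i_sorted = np.asarray(pairs_i)[order]

    def advance(idx: float) -> float:
        # f at the nearest aligned j
        pos = int(np.clip(np.searchsorted(j_sorted, idx), 0, len(j_sorted) - 1))
        if pos > 0 and abs(j_sorted[pos - 1] - idx) < abs(j_sorted[pos] - idx):
            pos -= 1
        return float(i_sorted[pos])

    visited = [float(min(pairs_j.min(), pairs_i.min()))]
    current = visited[0]
    for _ in range(n):
        nxt = advance(current)
        if nxt > n:
            break
        if any(abs(nxt - v) <= 1.0 for v in visited):
            break  # orbit closed (circular alignment wrapped back)
        visited.append(nxt)
        current = nxt
    boundaries = sorted(visited)
    if len(boundaries) >= 3:
        median_unit = float(np.median(np.diff(boundaries)))
        if n - boundaries[-1] + 1 < median_unit / 2:
            boundaries.pop()  # tail shorter than half a unit: merge into last
    ranges = []
    for idx, b in enumerate(boundaries):
        start = int(round(b))
        end = int(round(boundaries[idx + 1])) - 1 if idx + 1 < len(boundaries) else n
        if end >= start:
            ranges.append((start, end))
    return ranges


def build_report(
    result: ScanResult,
    model: NoiseModel | None = None,
    z_floor: float | None = None,
    unwrap: bool = False,
) -> dict:
    """Assemble the JSON-ready symmetry report for one scan.

    Without a calibration model the Z fields are "NA" and the
    classification "uncalibrated". ``unwrap`` switches reported group
    angles to the presentation convention where angles cluster near
    360 degrees instead of near 0 (plotting only; stored values keep
    the (-180, 180] convention).
    """
    best = result.best
    report: dict = {
        "label": result.label,
        "n_residues": result.n_residues,
        "best_shift": best.shift,
        "best_t_score": best.t_score,
        "n_aligned": best.n_aligned,
        "average_shift": best.average_shift,
        "config": result.config.to_dict(),
    }
    if best.axis is not None:
        report["best_axis"] = {
            "angle_deg": best.axis.angle_deg,
            "translation_along_axis": best.axis.translation_along_axis,
            "direction": best.axis.direction.tolist(),
            "point": best.axis.point.tolist(),
        }
    if model is None:
        report["best_z"] = "NA"
        report["classification"] = "uncalibrated"
    else:
        z = (
            best.z_score
            if best.z_score is not None
            else z_score(best.t_score, result.n_residues, model)
        )
        report["best_z"] = z
        report["symmetric_at_8"] = classify_symmetric(z, PERMISSIVE_Z)
        report["symmetric_at_10"] = classify_symmetric(z, STRICT_Z)
        report["classification"] = (
            "symmetric" if report["symmetric_at_8"] else "not symmetric"
        )
        floor = PERMISSIVE_Z if z_floor is None else z_floor
        groups = group_by_axis(result, floor)
        report["angle_groups"] = [
            {
                "n_members": len(grp),
                "top_angle_deg": _present_angle(grp[0].axis.angle_deg, unwrap),
                "top_translation": grp[0].axis.translation_along_axis,
                "top_z": grp[0].z_score,
                "min_average_shift": min(r.average_shift for r in grp),
            }
            for grp in groups
        ]
    try:
        i, j = best.original_pairs()
        units = derive_repeat_units(i, j, result.n_residues)
        report["repeat_units"] = [[int(a), int(b)] for a, b in units]
    except PreconditionError as exc:
        report["repeat_units"] = str(exc)
    return report


def _present_angle(angle_deg: float, unwrap: bool) -> float:
    if unwrap and angle_deg < 0:
        return angle_deg + 360.0
    return angle_deg
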