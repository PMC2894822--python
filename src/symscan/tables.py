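"""Tabular and file output of scan results.

One TSV row per circular shift (always N - 3 rows), a JSON summary of
the best alignment and classification, an optional two-row aligned-pair
text file, and a 3x4 transform text file ("r r r t" rows).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .geometry import RigidTransform
from .scan import ScanRecord, ScanResult

SCAN_COLUMNS = [
    "shift",
    "n_aligned",
    "t_score",
    "z_score",
    "angle_deg",
    "translation",
    "axis_dir_x",
    "axis_dir_y",
    "axis_dir_z",
    "axis_point_x",
    "axis_point_y",
    "axis_point_z",
    "average_shift",
    "is_noise",
]


def _record_row(rec: ScanRecord) -> dict:
    axis = rec.axis
    return {
        "shift": rec.shift,
        "n_aligned": rec.n_aligned,
        "t_score": rec.t_score,
        "z_score": "NA" if rec.z_score is None else rec.z_score,
        "angle_deg": np.nan if axis is None else axis.angle_deg,
        "translation": np.nan if axis is None else axis.translation_along_axis,
        "axis_dir_x": np.nan if axis is None else axis.direction[0],
        "axis_dir_y": np.nan if axis is None else axis.direction[1],
        "axis_dir_z": np.nan if axis is None else axis.direction[2],
        "axis_point_x": np.nan if axis is None else axis.point[0],
        "axis_point_y": np.nan if axis is None else axis.point[1],
        "axis_point_z": np.nan if axis is None else axis.point[2],
        "average_shift": rec.average_shift,
        "is_noise": "NA" if rec.is_noise is None else rec.is_noise,
    }


def scan_frame(result: ScanResult) -> pd.DataFrame:
    """Per-shift scan table as a DataFrame (column order frozen)."""
    return pd.DataFrame([_record_row(r) for r in result.records])[SCAN_COLUMNS]


def write_scan_table(result: ScanResult, path: str | Path) -> None:
    """Write the per-shift TSV; floats keep 8 significant digits."""
    path = Path(path)
    try:
        scan_frame(result).to_csv(path, sep="\t", index=False, float_format="%.8g")
    except OSError as exc:
        raise PreconditionError(f"cannot write scan table to {path}: {exc}") from exc


def read_scan_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=_coerce) + "\n")


def _coerce(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_alignment(result: ScanResult, path: str | Path) -> None:
    """Best alignment as two aligned index rows (original indices)."""
    best = result.best
    i, j = best.original_pairs()
    lines = [
        f"# {result.label}  shift={best.shift}  n_aligned={best.n_aligned}",
        "A: " + " ".join(str(v) for v in i),
        "B: " + " ".join(str(v) for v in j),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_transform(transform: RigidTransform, path: str | Path) -> None:
    """3 rows of 'r r r t' text."""
    rows = [
        f"{transform.rotation[r, 0]: .9f} {transform.rotation[r, 1]: .9f} "
        f"{transform.rotation[r, 2]: .9f} {transform.translation[r]: .9f}"
        for r in range(3)
    ]
    Path(path).write_text("\n".join(rows) + "\n")


def read_transform(path: str | Path) -> RigidTransform:
    rows = np.loadtxt(path)
    if rows.shape != (3, 4):
        raise PreconditionError(f"{path}: expected 3x4 transform text")
    return RigidTransform(rows[:, :3], rows[:, 3])
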