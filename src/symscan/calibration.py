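"""Size-dependent noise calibration and Z-scores.

Raw T-scores grow with protein size even for entirely asymmetric
structures, so symmetry is judged on a Z-score against the background of
'noise' alignments — refined self-alignments whose rotation axis
disagrees with the best one and that pair nothing near the diagonal.

Calibration pools the noise T-scores of a batch of structures, takes the
mean and standard deviation inside an 11-residue sliding window of
protein sizes, and fits the three-parameter saturating exponential

    y(N) = a + b * (1 - exp(-c * N))

separately to the mean and the standard-deviation series. Then

    Z(T, N) = (T - mean_curve(N)) / sd_curve(N),

and a structure is called symmetric when the Z of its best alignment
exceeds a cutoff; 8 (permissive) and 10 (strict) are both reported.

Structures of the all-alpha and all-beta classes tend to have elevated
noise T-scores (helix bundles, beta sandwiches); they can be excluded
from calibration via a caller-supplied class label.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConvergenceError, PreconditionError
from .scan import ScanResult

DEFAULT_WINDOW = 11
EXCLUDED_CLASSES = frozenset({"all-alpha", "all-beta"})


def _saturating_exp(n, a, b, c):
    return a + b * (1.0 - np.exp(-c * n))


@dataclass(frozen=True)
class NoiseModel:
    """Fitted background curves: T-score mean and spread vs protein size."""

    mean_params: tuple[float, float, float]
    sd_params: tuple[float, float, float]
    window_size: int = DEFAULT_WINDOW
    size_range: tuple[int, int] = (0, 0)
    n_points: int = 0
    residual_norm: float = 0.0
    provenance: str = ""

    def mean_curve(self, n) -> np.ndarray | float:
        n = np.clip(n, *self.size_range) if self.size_range != (0, 0) else n
        return _saturating_exp(np.asarray(n, dtype=float), *self.mean_params)

    def sd_curve(self, n) -> np.ndarray | float:
        n = np.clip(n, *self.size_range) if self.size_range != (0, 0) else n
        return _saturating_exp(np.asarray(n, dtype=float), *self.sd_params)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": "y = a + b * (1 - exp(-c * N))",
            "mean_params": list(self.mean_params),
            "sd_params": list(self.sd_params),
            "window_size": self.window_size,
            "size_range": list(self.size_range),
            "n_points": self.n_points,
            "residual_norm": self.residual_norm,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NoiseModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean_params=tuple(payload["mean_params"]),
            sd_params=tuple(payload["sd_params"]),
            window_size=payload["window_size"],
            size_range=tuple(payload["size_range"]),
            n_points=payload.get("n_points", 0),
            residual_norm=payload.get("residual_norm", 0.0),
            provenance=payload.get("provenance", ""),
        )


def collect_noise_stats(
    scans: list[tuple[ScanResult, str]],
    window_size: int = DEFAULT_WINDOW,
    exclude_classes: bool = True,
    min_points: int = 5,
) -> pd.DataFrame:
    """Pool noise T-scores and window them over protein size.

    Parameters
    ----------
    scans
        (noise-labelled ScanResult, class label) pairs. Labels
        "all-alpha" / "all-beta" are dropped when ``exclude_classes``;
        any other label ("other", SCOP class letters, ...) is kept.
    window_size
        Width (in residues) of the sliding window; 1 gives per-size
        raw statistics.

    Returns
    -------
    DataFrame with columns ``size`` (window center), ``mean_t``,
    ``sd_t``, ``n_obs``. Windows with fewer than ``min_points``
    observations are dropped.
    """
    sizes: list[int] = []
    tvals: list[np.ndarray] = []
    for result, class_label in scans:
        if exclude_classes and class_label in EXCLUDED_CLASSES:
            continue
        noise_t = np.array([r.t_score for r in result.noise_records()])
        if len(noise_t) < 2:
            continue
        sizes.append(result.n_residues)
        tvals.append(noise_t)
    if not sizes:
        raise PreconditionError(
            "no usable noise alignments (empty batch or all classes excluded)"
        )
    sizes_arr = np.array(sizes)
    half = (window_size - 1) // 2
    rows = []
    for center in range(sizes_arr.min(), sizes_arr.max() + 1):
        in_win = np.abs(sizes_arr - center) <= half
        if not np.any(in_win):
            continue
        pooled = np.concatenate([tvals[idx] for idx in np.flatnonzero(in_win)])
        if len(pooled) < min_points:
            continue
        rows.append(
            {
                "size": center,
                "mean_t": float(pooled.mean()),
                "sd_t": float(pooled.std(ddof=1)) if len(pooled) > 1 else 0.0,
                "n_obs": int(len(pooled)),
            }
        )
    if not rows:
        raise PreconditionError("no window reached the minimum observation count")
    return pd.DataFrame(rows)


def _fit_series(n: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float, float], float]:
    # fixed, documented initialization => deterministic fit
    a0 = float(np.min(y))
    b0 = float(np.max(y) - np.min(y))
    c0 = 1.0 / float(np.median(n))
    try:
        params, _ = curve_fit(
            _saturating_exp,
            n,
            y,
            p0=(a0, max(b0, 1e-6), c0),
            maxfev=20000,
            bounds=((-np.inf, 0.0, 1e-9), (np.inf, np.inf, 1.0)),
        )
    except (RuntimeError, ValueError) as exc:
        raise ConvergenceError(
            f"exponential fit failed: {exc}",
            {"p0": (a0, b0, c0), "n_points": len(n)},
        ) from exc
    resid = float(np.linalg.norm(_saturating_exp(n, *params) - y))
    return tuple(float(p) for p in params), resid


def fit_noise_model(stats: pd.DataFrame, provenance: str = "") -> NoiseModel:
    """Fit the saturating exponential to the windowed mean and sd series."""
    if len(stats) < 6 or stats["size"].nunique() < 3:
        raise PreconditionError(
            "need at least 6 windows spanning at least 3 distinct sizes"
        )
    n = stats["size"].to_numpy(dtype=float)
    mean_params, r1 = _fit_series(n, stats["mean_t"].to_numpy(dtype=float))
    sd_params, r2 = _fit_series(n, stats["sd_t"].to_numpy(dtype=float))
    model = NoiseModel(
        mean_params=mean_params,
        sd_params=sd_params,
        window_size=DEFAULT_WINDOW,
        size_range=(int(stats["size"].min()), int(stats["size"].max())),
        n_points=int(len(stats)),
        residual_norm=float(np.hypot(r1, r2)),
        provenance=provenance,
    )
    lo, hi = model.size_range
    grid = np.linspace(lo, hi, 64)
    if np.any(model.mean_curve(grid) <= 0) or np.any(model.sd_curve(grid) <= 0):
        raise ConvergenceError(
            "fitted noise curves are not positive over the calibrated range",
            {"mean_params": mean_params, "sd_params": sd_params},
        )
    return model


def z_score(t: float, n: int, model: NoiseModel) -> float:
    """Z = (T - mean_curve(N)) / sd_curve(N); N clamps to the fitted range."""
    sd = float(model.sd_curve(n))
    if sd <= 0:
        raise PreconditionError(f"sd curve non-positive at N={n}")
    return (t - float(model.mean_curve(n))) / sd


def classify_symmetric(best_z: float, cutoff: float) -> bool:
    """Strictly above the cutoff counts as symmetric."""
    if cutoff <= 0:
        raise PreconditionError("cutoff must be positive")
    return best_z > cutoff


def apply_calibration(result: ScanResult, model: NoiseModel) -> ScanResult:
    """Attach a Z-score to every record of a scan result."""
    records = tuple(
        replace(rec, z_score=z_score(rec.t_score, result.n_residues, model))
        for rec in result.records
    )
    return replace(result, records=records)


def calibration_hash(labels: list[str]) -> str:
    """Short provenance hash of the calibration set membership."""
    digest = hashlib.sha256("\n".join(sorted(labels)).encode())
    return digest.hexdigest()[:16]
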