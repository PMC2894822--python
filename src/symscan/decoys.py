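"""Decoy-based noise calibration.

The Z-score needs a background model of noise T-scores versus protein
size. Published constants are not shipped; instead the model is always
fitted from a batch of asymmetric decoys (or any user-supplied
structures) and stored as a versioned JSON artifact. Random-coil decoys
generated here are labelled "other" (mixed class), so the all-alpha /
all-beta exclusion pathway stays available for real structures.
"""

from __future__ import annotations

import numpy as np

from .calibration import (
    NoiseModel,
    calibration_hash,
    collect_noise_stats,
    fit_noise_model,
)
from .refine import ScanConfig
from .scan import ScanResult, alignment_scan, label_noise
from .synthetic import GeneratorSpec, make_random_coil
from .trace import CaTrace


def scan_and_label(trace: CaTrace, cfg: ScanConfig | None = None) -> ScanResult:
    """Scan a trace and attach noise labels in one step."""
    return label_noise(alignment_scan(trace, cfg))


def decoy_traces(
    n_decoys: int,
    size_range: tuple[int, int] = (80, 250),
    seed: int = 0,
) -> list[CaTrace]:
    """Random-coil decoys with sizes uniform over ``size_range``."""
    rng = np.random.default_rng(seed)
    traces = []
    for idx in range(n_decoys):
        n_res = int(rng.integers(size_range[0], size_range[1] + 1))
        # unit_length carries the residue count for the coil kind
        spec = GeneratorSpec(
            kind="random_coil",
            n_units=1,
            unit_length=n_res,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        traces.append(make_random_coil(spec))
    return traces


def calibrate_from_decoys(
    n_decoys: int = 200,
    size_range: tuple[int, int] = (80, 250),
    seed: int = 0,
    cfg: ScanConfig | None = None,
    progress=None,
) -> NoiseModel:
    """Generate decoys, scan them, and fit the noise model.

    ``progress`` may be a callable taking (done, total) for reporting.
    """
    traces = decoy_traces(n_decoys, size_range, seed)
    scans = []
    for idx, trace in enumerate(traces):
        scans.append((scan_and_label(trace, cfg), "other"))
        if progress is not None:
            progress(idx + 1, len(traces))
    stats = collect_noise_stats(scans)
    return fit_noise_model(
        stats, provenance=calibration_hash([t.label for t in traces])
    )
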