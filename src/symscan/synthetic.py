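"""Synthetic Cα traces with known symmetry.

The generators produce the three structure classes the scan is built to
distinguish: closed n-fold rotationally symmetric rings (propellers,
trefoils, barrels), open helical solenoids (superhelices, beta-helices,
leucine-rich repeats), and asymmetric random-coil decoys for the noise
calibration. Everything is a pure function of its spec (seed included).

Construction of the symmetric kinds: one repeating unit is a closed loop
sampled in a local frame, and copies are laid down by applying the
generating screw (rotation about z by the twist, translation along z by
the rise) once per unit. With zero noise the resulting point set is
*exactly* invariant under the generating operation — the strongest
available oracle for the whole detection pipeline. The loop radius is
chosen so consecutive Cα points sit near the standard 3.8 Å virtual bond
length, keeping d0-scaled scores realistic.

Indel edits are applied after symmetry construction, so the ground-truth
symmetry of the untouched residues is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PreconditionError
from .trace import CaTrace, ResidueId

CA_BOND = 3.8  # Å, trans Calpha-Calpha virtual bond
MIN_NONLOCAL_DIST = 4.0  # Å, excluded volume for the random coil


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic trace.

    kind
        "cyclic", "helical" or "random_coil".
    n_units, unit_length
        Number of repeating units and residues per unit (symmetric kinds);
        random coils use n_residues = n_units * unit_length.
    radius
        Extra offset of the unit loop from the symmetry axis, Å.
    rise, twist_deg
        Per-unit screw: translation along and rotation about the axis.
        Cyclic kind ignores these (twist = 360/n_units, rise = 0).
    noise_sd
        Isotropic Gaussian displacement per atom, Å.
    indels
        (unit index, edit) pairs; positive edit inserts that many
        residues into the unit, negative deletes.
    """

    kind: str = "cyclic"
    n_units: int = 4
    unit_length: int = 20
    radius: float = 4.0
    rise: float = 4.8
    twist_deg: float = 100.0
    noise_sd: float = 0.0
    indels: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("cyclic", "helical", "random_coil"):
            raise PreconditionError(f"unknown generator kind {self.kind!r}")
        if self.kind != "random_coil" and self.n_units < 2:
            raise PreconditionError("symmetric kinds need n_units >= 2")
        if self.noise_sd < 0:
            raise PreconditionError("noise_sd must be >= 0")
        if self.unit_length < 4:
            raise PreconditionError("unit_length must be >= 4")

    @property
    def n_residues(self) -> int:
        return self.n_units * self.unit_length


def _wound_coords(
    n_units: int, unit_length: int, radius_offset: float, twist_deg: float, rise: float
) -> np.ndarray:
    """Continuous tube winding: one poloidal loop per unit, screw applied
    per residue.

    Residue g (0-based) sits at Rz(twist * g / L) applied to the unit
    loop point loop(g mod L), plus rise * g / L along z. Advancing by one
    full unit (g -> g + L) is then *exactly* the generating screw —
    rotation by ``twist_deg`` about z plus ``rise`` along z — while
    consecutive residues stay near the 3.8 Å virtual bond because the
    loop closes smoothly across the unit boundary.
    """
    L = unit_length
    r = CA_BOND * L / (2.0 * np.pi)
    g = np.arange(n_units * L)
    tau = (g % L) / L
    # unit loop in the rotating frame: circle in the x-z plane, offset +x
    lx = radius_offset + r + r * np.cos(2 * np.pi * tau)
    lz = r * np.sin(2 * np.pi * tau)
    theta = np.radians(twist_deg) * g / L
    x = lx * np.cos(theta)
    y = lx * np.sin(theta)
    z = lz + rise * g / L
    return np.column_stack([x, y, z])


def _apply_noise_and_indels(
    coords: np.ndarray, spec: GeneratorSpec, rng: np.random.Generator
) -> np.ndarray:
    for unit_idx, edit in spec.indels:
        if not 0 <= unit_idx < spec.n_units:
            raise PreconditionError(f"indel unit index {unit_idx} out of range")
        start = unit_idx * spec.unit_length
        if edit < 0:  # deletion
            take = min(-edit, spec.unit_length - 1)
            coords = np.delete(
                coords, np.arange(start, start + take), axis=0
            )
        elif edit > 0:  # insertion: a jittered bridge inside the unit
            anchor_a = coords[start + spec.unit_length // 2 - 1]
            anchor_b = coords[start + spec.unit_length // 2]
            frac = np.linspace(0, 1, edit + 2)[1:-1, None]
            bridge = anchor_a + frac * (anchor_b - anchor_a)
            bridge = bridge + rng.normal(0.0, 1.5, size=bridge.shape)
            coords = np.insert(
                coords, start + spec.unit_length // 2, bridge, axis=0
            )
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
    return coords


def _as_trace(coords: np.ndarray, label: str) -> CaTrace:
    ids = tuple(ResidueId("A", i + 1) for i in range(len(coords)))
    return CaTrace(coords, ids, label)


def make_cyclic(spec: GeneratorSpec) -> CaTrace:
    """Closed ring with exact n-fold rotational symmetry about z."""
    if spec.kind != "cyclic":
        raise PreconditionError("spec.kind must be 'cyclic'")
    rng = np.random.default_rng(spec.seed)
    coords = _wound_coords(
        spec.n_units, spec.unit_length, spec.radius, 360.0 / spec.n_units, 0.0
    )
    coords = _apply_noise_and_indels(coords, spec, rng)
    return _as_trace(coords, f"cyclic_C{spec.n_units}_L{spec.unit_length}")


def make_helical(spec: GeneratorSpec) -> CaTrace:
    """Open solenoid: per-unit screw of twist about z plus rise along z."""
    if spec.kind != "helical":
        raise PreconditionError("spec.kind must be 'helical'")
    rng = np.random.default_rng(spec.seed)
    coords = _wound_coords(
        spec.n_units, spec.unit_length, spec.radius, spec.twist_deg, spec.rise
    )
    coords = _apply_noise_and_indels(coords, spec, rng)
    return _as_trace(
        coords,
        f"helical_{spec.n_units}x{spec.unit_length}"
        f"_rise{spec.rise:g}_twist{spec.twist_deg:g}",
    )


def make_random_coil(spec: GeneratorSpec, max_restarts: int = 200) -> CaTrace:
    """Self-avoiding random walk: 3.8 Å steps, >= 4 Å between non-neighbors.

    Step directions are drawn uniformly within a cone about the previous
    direction (persistence keeps the walk from trapping itself); on a
    dead end the walk backtracks, and after bounded restarts it fails.
    """
    if spec.kind != "random_coil":
        raise PreconditionError("spec.kind must be 'random_coil'")
    n = spec.n_residues
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_restarts):
        pts = np.zeros((n, 3))
        direction = _random_unit(rng)
        pts[1] = pts[0] + CA_BOND * direction
        ok = True
        i = 2
        dead_ends = 0
        while i < n:
            placed = False
            for _try in range(60):
                step = _cone_step(direction, rng)
                cand = pts[i - 1] + CA_BOND * step
                d2 = np.sum((pts[: i - 1] - cand) ** 2, axis=1)
                if np.all(d2 >= MIN_NONLOCAL_DIST**2):
                    pts[i] = cand
                    direction = step
                    placed = True
                    break
            if placed:
                i += 1
                continue
            dead_ends += 1
            if dead_ends > 50:
                ok = False
                break
            back = min(5, i - 2)
            i -= back
            direction = _random_unit(rng)
        if ok:
            return _as_trace(pts, f"coil_N{n}_seed{spec.seed}")
    raise PreconditionError(
        f"self-avoiding walk failed after {max_restarts} restarts (N={n})"
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _cone_step(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit vector at 60-120 degrees from ``direction`` (chain-like bend)."""
    # cos(angle) uniform in [-0.5, 0.5]: bond angles 60..120 deg, which
    # automatically keeps second neighbors >= ~3.8 A away
    c = rng.uniform(-0.5, 0.5)
    s = np.sqrt(1.0 - c * c)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal frame around direction
    a = np.array([1.0, 0.0, 0.0])
    if abs(direction[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return c * direction + s * (np.cos(phi) * e1 + np.sin(phi) * e2)


def generate(spec: GeneratorSpec) -> CaTrace:
    """Dispatch on spec.kind."""
    if spec.kind == "cyclic":
        return make_cyclic(spec)
    if spec.kind == "helical":
        return make_helical(spec)
    return make_random_coil(spec)
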