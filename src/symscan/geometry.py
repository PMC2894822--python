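"""Rigid-body superposition and screw-axis decomposition.

Any proper rigid motion of 3-space is a screw: a rotation by some angle
about an axis (a line, not just a direction) combined with a translation
along that axis (Chasles' theorem). The scan superposes a structure onto
its circularly permuted copy and reads the symmetry element straight off
the resulting transform: rotation angle, axis direction, a point the
axis passes through, and the helical translation (pitch per application).

Conventions
-----------
* Transforms act as ``x -> R @ x + t`` on column 3-vectors.
* Angles are reported signed in (-180, 180] degrees. A rotation matrix
  alone determines only |angle| and the axis up to a simultaneous sign
  flip; we canonicalize the direction so that its dot product with a
  caller-supplied reference direction (the scan uses the best
  alignment's axis, else +z) is non-negative, then sign the angle by the
  right-hand rule about that direction.
* Near-identity transforms (|angle| below ``IDENTITY_ANGLE_DEG``) have
  no well-defined axis point; the direction is taken from the
  translation vector (pure-translation limit) and the point from a
  caller-supplied reference (typically the structure centroid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import PreconditionError
from .pairing import ResiduePairing

#: below this rotation magnitude a transform is treated as a pure translation
IDENTITY_ANGLE_DEG = 1.0

_ORTHONORMAL_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise PreconditionError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise PreconditionError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise PreconditionError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) coordinate array."""
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def angle_deg(self) -> float:
        """Unsigned rotation magnitude, arccos((trace - 1) / 2), degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class ScrewAxis:
    """Screw decomposition of a rigid transform.

    ``direction`` is a unit vector; ``point`` lies on the axis;
    ``angle_deg`` is the signed rotation in (-180, 180] about
    ``direction`` (right-hand rule); ``translation_along_axis`` is the
    displacement along the axis per application of the transform, in Å.
    """

    direction: np.ndarray
    point: np.ndarray
    angle_deg: float
    translation_along_axis: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        p = np.asarray(self.point, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise PreconditionError("screw axis direction must be a unit vector")
        object.__setattr__(self, "direction", d / np.linalg.norm(d))
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "angle_deg", float(self.angle_deg))
        object.__setattr__(
            self, "translation_along_axis", float(self.translation_along_axis)
        )


def superpose_points(
    ref: np.ndarray, mov: np.ndarray
) -> tuple[RigidTransform, float, bool]:
    """Least-squares optimal proper superposition of ``mov`` onto ``ref``.

    Kabsch's SVD solution with the determinant sign correction that
    excludes reflections: if the raw SVD product has determinant -1, the
    singular direction with the smallest singular value is flipped.

    Returns the transform, the RMSD it achieves, and a flag marking
    degenerate (rank-deficient, e.g. collinear) point sets — these are
    still superposed, but the in-plane orientation is not unique.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise PreconditionError("point sets must be matching (N, 3) arrays")
    if len(ref) < 3:
        raise PreconditionError("superposition needs at least 3 points")
    cref = ref.mean(axis=0)
    cmov = mov.mean(axis=0)
    H = (mov - cmov).T @ (ref - cref)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = cref - R @ cmov
    moved = mov @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    # rank < 3 covariance: collinear or coplanar-degenerate input
    degenerate = bool(S[-1] < 1e-9 * max(S[0], 1.0) or S[1] < 1e-12)
    return RigidTransform(R, t), rmsd, degenerate


def kabsch_superpose(
    pairs: ResiduePairing, trace_a, trace_b
) -> tuple[RigidTransform, float]:
    """Superpose trace B onto trace A over the aligned residue pairs.

    ``trace_a`` / ``trace_b`` may be :class:`~symscan.trace.CaTrace`
    objects or bare (N, 3) arrays; pairing indices are 1-based.
    """
    if len(pairs) < 3:
        raise PreconditionError("superposition needs at least 3 aligned pairs")
    xa = getattr(trace_a, "coords", trace_a)
    xb = getattr(trace_b, "coords", trace_b)
    if pairs.i.max() > len(xa) or pairs.j.max() > len(xb):
        raise PreconditionError("pairing indexes residues outside the traces")
    transform, rmsd, _ = superpose_points(xa[pairs.i - 1], xb[pairs.j - 1])
    return transform, rmsd


def _canonical_sign(direction: np.ndarray, reference: np.ndarray) -> float:
    d = float(np.dot(direction, reference))
    if abs(d) > 1e-12:
        return 1.0 if d > 0 else -1.0
    # reference orthogonal to axis: fall back to a fixed lexicographic rule
    for comp in direction:
        if abs(comp) > 1e-12:
            return 1.0 if comp > 0 else -1.0
    return 1.0


def decompose_transform(
    transform: RigidTransform,
    reference_axis: np.ndarray | None = None,
    reference_point: np.ndarray | None = None,
) -> ScrewAxis:
    """Decompose a rigid transform into its screw elements.

    The rotation angle/axis come from the rotation matrix (rotation
    vector); the translation splits into a component parallel to the
    axis (the helical translation) and an in-plane component absorbed by
    the axis position, obtained as the minimum-norm solution of
    ``(R - I) p = -t_perp`` so that points on the axis move only along it.

    ``reference_axis`` controls the sign canonicalization (default +z);
    ``reference_point`` supplies the axis point in the pure-translation
    limit where the axis position is ill-defined (default origin).
    """
    R = transform.rotation
    t = transform.translation
    ref_axis = np.array([0.0, 0.0, 1.0]) if reference_axis is None else (
        np.asarray(reference_axis, dtype=float)
    )
    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))

    if angle < IDENTITY_ANGLE_DEG:
        # pure-translation limit: axis direction from t, point from caller
        tnorm = float(np.linalg.norm(t))
        if tnorm > 1e-12:
            direction = t / tnorm
        else:
            direction = ref_axis / np.linalg.norm(ref_axis)
        sign = _canonical_sign(direction, ref_axis)
        direction = sign * direction
        point = (
            np.zeros(3) if reference_point is None else np.asarray(reference_point)
        )
        # angle signed consistently even when tiny
        signed_angle = sign * angle if tnorm > 1e-12 else angle
        return ScrewAxis(direction, point, signed_angle, float(np.dot(t, direction)))

    direction = rotvec / np.linalg.norm(rotvec)
    sign = _canonical_sign(direction, ref_axis)
    direction = sign * direction
    signed_angle = sign * angle
    if signed_angle <= -180.0:  # map -180 to +180 (same rotation)
        signed_angle += 360.0

    t_par = np.dot(t, direction) * direction
    t_perp = t - t_par
    # minimum-norm p with (R - I) p = -t_perp; (R - I) is rank 2, its null
    # space is the axis direction, so lstsq picks the point closest to origin
    point, *_ = np.linalg.lstsq(R - np.eye(3), -t_perp, rcond=None)
    return ScrewAxis(direction, point, signed_angle, float(np.dot(t, direction)))


def compose_screw(axis: ScrewAxis) -> RigidTransform:
    """Rebuild the rigid transform generated by a screw axis."""
    u = axis.direction
    R = Rotation.from_rotvec(np.radians(axis.angle_deg) * u).as_matrix()
    t = axis.translation_along_axis * u + (np.eye(3) - R) @ axis.point
    return RigidTransform(R, t)


def axis_cosine(a: ScrewAxis, b: ScrewAxis) -> float:
    """Cosine of the angle between two axis directions (in [-1, 1])."""
    return float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
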