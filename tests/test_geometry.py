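"""Superposition and screw-decomposition oracles.

The round-trip tests are construct-then-recover: a screw is built from
known parameters, composed into a rigid transform, and the decomposition
must return the same parameters. Kabsch optimality is checked against a
brute-force sweep of random rigid placements.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from symscan import (
    PreconditionError,
    ResiduePairing,
    RigidTransform,
    ScrewAxis,
    axis_cosine,
    compose_screw,
    decompose_transform,
    kabsch_superpose,
    superpose_points,
)


def random_screws(rng, n, angle_range=(1.0, 179.0)):
    for _ in range(n):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        angle = rng.uniform(*angle_range) * rng.choice([-1.0, 1.0])
        point = rng.uniform(-30, 30, size=3)
        # remove the axis-parallel component so `point` is a canonical-free
        # representative; any point on the line is equivalent
        pitch = rng.uniform(-5, 5)
        yield ScrewAxis(direction, point, angle, pitch)


def test_compose_decompose_round_trip_1000_random_screws(rng):
    for axis in random_screws(rng, 1000):
        t = compose_screw(axis)
        # decompose with the original direction as reference so the
        # sign convention matches the construction
        d = decompose_transform(t, reference_axis=axis.direction)
        t2 = compose_screw(d)
        assert np.allclose(t2.rotation, t.rotation, atol=1e-6)
        assert np.allclose(t2.translation, t.translation, atol=1e-6)
        assert d.angle_deg == pytest.approx(axis.angle_deg, abs=1e-6)
        assert d.translation_along_axis == pytest.approx(
            axis.translation_along_axis, abs=1e-6
        )
        assert np.allclose(d.direction, axis.direction, atol=1e-6)
        # the axis point must itself move only along the axis
        moved = t.apply(d.point[None, :])[0]
        off_axis = (moved - d.point) - np.dot(
            moved - d.point, d.direction
        ) * d.direction
        assert np.linalg.norm(off_axis) < 1e-6


def test_decompose_angle_matches_trace_formula(rng):
    for axis in random_screws(rng, 50):
        t = compose_screw(axis)
        d = decompose_transform(t)
        assert abs(d.angle_deg) == pytest.approx(t.angle_deg(), abs=1e-9)


def test_identity_transform_decomposes_to_zero():
    d = decompose_transform(RigidTransform.identity())
    assert d.angle_deg == pytest.approx(0.0)
    assert d.translation_along_axis == pytest.approx(0.0)


def test_pure_180_rotation_about_z():
    R = Rotation.from_euler("z", 180, degrees=True).as_matrix()
    d = decompose_transform(RigidTransform(R, np.zeros(3)))
    assert abs(d.angle_deg) == pytest.approx(180.0, abs=1e-9)
    assert abs(d.direction[2]) == pytest.approx(1.0, abs=1e-9)
    assert d.translation_along_axis == pytest.approx(0.0, abs=1e-9)
    # axis point lies on the z-axis
    assert np.hypot(d.point[0], d.point[1]) < 1e-9


def test_near_identity_is_pure_translation_limit():
    t = RigidTransform(np.eye(3), np.array([0.0, 0.0, 4.4]))
    centroid = np.array([1.0, 2.0, 3.0])
    d = decompose_transform(t, reference_point=centroid)
    assert d.angle_deg == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(d.direction, [0, 0, 1])
    assert d.translation_along_axis == pytest.approx(4.4)
    assert np.allclose(d.point, centroid)


def test_kabsch_identity_on_exact_copy(rng):
    pts = rng.normal(size=(12, 3)) * 10
    pairing = ResiduePairing.identity(12)
    t, rmsd = kabsch_superpose(pairing, pts, pts.copy())
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(t.translation, 0.0, atol=1e-9)


def test_kabsch_recovers_constructed_transform(rng):
    pts = rng.normal(size=(15, 3)) * 8
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    shift = np.array([1.0, 2.0, 3.0])
    moved = pts @ R.T + shift
    t, rmsd = kabsch_superpose(ResiduePairing.identity(15), pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    # recovered transform is the inverse map
    assert np.allclose(t.rotation, R.T, atol=1e-9)
    assert np.allclose(t.translation, -R.T @ shift, atol=1e-9)


def test_kabsch_beats_ten_thousand_random_rigid_placements(rng):
    pts = rng.normal(size=(10, 3)) * 6
    noisy = pts + rng.normal(scale=0.8, size=pts.shape)
    _, best_rmsd, _ = superpose_points(pts, noisy)
    rots = Rotation.random(10_000, rng=7)
    # random placements: rotate about the centroid, add a random offset,
    # and measure RMSD directly (vectorized brute-force sweep)
    centered = noisy - noisy.mean(axis=0)
    offsets = rng.normal(scale=2.0, size=(10_000, 3))
    rotated = np.einsum("rij,nj->rni", rots.as_matrix(), centered)
    target = pts - pts.mean(axis=0)
    rmsds = np.sqrt(
        np.mean(
            np.sum((rotated + offsets[:, None, :] - target[None]) ** 2, axis=2),
            axis=1,
        )
    )
    assert best_rmsd <= rmsds.min() + 1e-12


def test_kabsch_rmsd_invariant_under_common_rigid_motion(rng):
    a = rng.normal(size=(20, 3)) * 10
    b = a + rng.normal(scale=1.0, size=a.shape)
    _, rmsd0, _ = superpose_points(a, b)
    R = Rotation.random(rng=3).as_matrix()
    shift = np.array([5.0, -7.0, 2.0])
    _, rmsd1, _ = superpose_points(a @ R.T + shift, b @ R.T + shift)
    assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


def test_kabsch_agrees_with_scipy_align_vectors(rng):
    a = rng.normal(size=(25, 3)) * 10
    b = a + rng.normal(scale=0.5, size=a.shape)
    t, rmsd, _ = superpose_points(a, b)
    rot, rssd = Rotation.align_vectors(a - a.mean(axis=0), b - b.mean(axis=0))
    assert np.allclose(t.rotation, rot.as_matrix(), atol=1e-8)
    assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)


def test_kabsch_excludes_reflections(rng):
    # a mirrored cloud must still come back with a proper rotation
    a = rng.normal(size=(10, 3)) * 5
    b = a.copy()
    b[:, 0] *= -1
    t, _, _ = superpose_points(a, b)
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)


def test_degenerate_collinear_points_flagged():
    a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    t, rmsd, degenerate = superpose_points(a, a.copy())
    assert degenerate
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_rejects_too_few_pairs():
    pts = np.zeros((2, 3))
    with pytest.raises(PreconditionError):
        superpose_points(pts, pts)


def test_axis_cosine_values():
    z = ScrewAxis(np.array([0, 0, 1.0]), np.zeros(3), 90.0, 0.0)
    x = ScrewAxis(np.array([1.0, 0, 0]), np.zeros(3), 90.0, 0.0)
    tilted = ScrewAxis(
        np.array([np.sin(np.radians(20)), 0, np.cos(np.radians(20))]),
        np.zeros(3), 90.0, 0.0,
    )
    assert axis_cosine(z, z) == pytest.approx(1.0)
    assert axis_cosine(z, x) == pytest.approx(0.0)
    # a 20-degree tilt falls below the same-axis cutoff of 0.95
    assert axis_cosine(z, tilted) == pytest.approx(np.cos(np.radians(20)), abs=1e-12)
    assert axis_cosine(z, tilted) < 0.95


def test_rigid_transform_rejects_reflection():
    refl = np.diag([1.0, 1.0, -1.0])
    with pytest.raises(PreconditionError):
        RigidTransform(refl, np.zeros(3))
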