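"""Alignment scan: seeding, noise labelling, grouping, determinism."""

import numpy as np
import pytest

from symscan import (
    GeneratorSpec,
    PreconditionError,
    ResiduePairing,
    ScanConfig,
    ScrewAxis,
    alignment_scan,
    average_shift,
    group_by_axis,
    initial_pairing,
    label_noise,
    make_cyclic,
)
from symscan.scan import ScanRecord, ScanResult, permuted_indices


class TestInitialPairing:
    def test_five_residues_shift_one(self):
        p = initial_pairing(5, 1)
        assert list(zip(p.i, p.j)) == [(2, 1), (3, 2), (4, 3), (5, 4)]

    def test_five_residues_shift_four_single_pair(self):
        p = initial_pairing(5, 4)
        assert list(zip(p.i, p.j)) == [(5, 1)]

    def test_scan_minimum_seed_is_three_pairs(self):
        assert len(initial_pairing(100, 97)) == 3

    def test_out_of_range_shift_rejected(self):
        with pytest.raises(PreconditionError):
            initial_pairing(10, 0)
        with pytest.raises(PreconditionError):
            initial_pairing(10, 10)

    def test_average_shift_of_initial_pairing_is_k(self):
        for k in (1, 7, 50):
            assert average_shift(initial_pairing(80, k)) == pytest.approx(float(k))


def test_average_shift_arithmetic():
    pairing = ResiduePairing.from_pairs([(5, 1), (10, 2)])
    assert average_shift(pairing) == pytest.approx(6.0)
    with pytest.raises(PreconditionError):
        average_shift(ResiduePairing.empty())


def test_permuted_indices_mapping():
    # position k+1 holds residue 1; positions 1..k hold the wrapped tail
    jorig = permuted_indices(10, 3)
    assert list(jorig) == [8, 9, 10, 1, 2, 3, 4, 5, 6, 7]


@pytest.fixture(scope="module")
def result(c4_trace):
    return alignment_scan(c4_trace)


class TestScanOnC4:
    def test_best_is_one_unit_shift_full_length(self, result):
        assert result.best.shift == 20
        assert result.best.t_score == pytest.approx(80.0, rel=0.01)
        assert abs(result.best.axis.angle_deg) == pytest.approx(90.0, abs=0.5)
        assert result.best.axis.translation_along_axis == pytest.approx(0.0, abs=0.1)

    def test_all_three_rotation_families_present(self, result):
        angles = {
            round(abs(r.axis.angle_deg))
            for r in result.records
            if r.axis is not None and r.t_score > 60
        }
        assert {90, 180} <= angles  # 270° reports as -90° in (-180, 180]

    def test_record_count_and_order(self, result):
        assert len(result.records) == 77  # N - 3
        assert [r.shift for r in result.records] == list(range(1, 78))

    def test_determinism_bitwise(self, c4_trace):
        r1 = alignment_scan(c4_trace)
        r2 = alignment_scan(c4_trace)
        assert [r.t_score for r in r1.records] == [r.t_score for r in r2.records]
        assert all(
            np.array_equal(a.pairing.i, b.pairing.i)
            and np.array_equal(a.pairing.j, b.pairing.j)
            for a, b in zip(r1.records, r2.records)
        )
        for a, b in zip(r1.records, r2.records):
            if a.transform is None:
                assert b.transform is None
                continue
            assert np.array_equal(a.transform.rotation, b.transform.rotation)
            assert np.array_equal(a.transform.translation, b.transform.translation)

    def test_average_shift_of_circular_ring_alignment(self):
        trace = make_cyclic(GeneratorSpec(kind="cyclic", n_units=7, unit_length=15))
        result = alignment_scan(trace)
        n, unit = len(trace), 15
        # the best alignment wraps: raw mean (i - j) lands within one
        # unit length of N/7
        assert abs(result.best.average_shift - n / 7) <= unit


def _axis(direction, angle):
    d = np.asarray(direction, dtype=float)
    return ScrewAxis(d / np.linalg.norm(d), np.zeros(3), angle, 0.0)


def _record(shift, axis, t, separations, z=None):
    i = np.arange(1, len(separations) + 1) + np.asarray(separations)
    j = np.arange(1, len(separations) + 1)
    pairing = ResiduePairing(i, j)
    return ScanRecord(
        shift, pairing, j.copy(),  # original index == position for hand-built records
        None, axis, t, float(np.mean(separations)), len(separations), z_score=z,
    )


def _manual_result(records, best_index):
    return ScanResult(tuple(records), best_index, "manual", 50, ScanConfig())


class TestLabelNoise:
    def make(self):
        best = _record(10, _axis([0, 0, 1], 90.0), 40.0, [10] * 5)
        same_axis = _record(11, _axis([0, 0, 1], 90.5), 20.0, [11] * 5)
        perp_clear = _record(12, _axis([1, 0, 0], 33.0), 5.0, [12] * 5)
        perp_near_diag = _record(13, _axis([1, 0, 0], 47.0), 5.0, [2, 12, 12, 12, 12])
        return _manual_result([best, same_axis, perp_clear, perp_near_diag], 0)

    def test_noise_definition_two_conditions(self):
        result = label_noise(self.make())
        flags = [r.is_noise for r in result.records]
        # best never noise; same-axis record not noise; perpendicular and
        # clear of the diagonal IS noise; perpendicular but touching the
        # diagonal is not
        assert flags == [False, False, True, False]


class TestGroupByAxis:
    def test_all_below_floor_gives_empty(self):
        rec = _record(5, _axis([0, 0, 1], 90.0), 10.0, [5] * 4, z=4.0)
        assert group_by_axis(_manual_result([rec], 0), z_floor=8.0) == []

    def test_single_peak_single_group(self):
        recs = [
            _record(5, _axis([0, 0, 1], 179.0), 30.0, [5] * 4, z=12.0),
            _record(6, _axis([0, 0, 1], -179.5), 28.0, [6] * 4, z=11.0),
        ]
        groups = group_by_axis(_manual_result(recs, 0), z_floor=8.0)
        assert len(groups) == 1  # 179 and -179.5 are 1.5° apart circularly
        assert len(groups[0]) == 2

    def test_distinct_angles_form_distinct_groups(self):
        recs = [
            _record(5, _axis([0, 0, 1], 90.0), 30.0, [5] * 4, z=12.0),
            _record(6, _axis([0, 0, 1], 180.0), 28.0, [6] * 4, z=11.0),
            _record(7, _axis([0, 0, 1], -90.0), 26.0, [7] * 4, z=10.5),
        ]
        groups = group_by_axis(_manual_result(recs, 0), z_floor=8.0)
        assert len(groups) == 3
        # sorted by smallest average shift
        assert [g[0].shift for g in groups] == [5, 6, 7]
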