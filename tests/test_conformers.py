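"""Geometry, sampling-schedule, and circular-statistics unit tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from nespec import (
    AngleSeries,
    DihedralSpec,
    Frame,
    SamplingSchedule,
    angular_histogram,
    compute_dihedral,
    compute_distance,
    decimation_indices,
    find_modes,
    gen_angle_series,
    saved_frame_times,
    TorsionModel,
    wrap_angle,
)
from nespec.conformers import read_xyz_frames, write_xyz_frames
from nespec.errors import (
    DegenerateGeometryError,
    NoDataError,
    UnknownAtomError,
)

SPEC = DihedralSpec("chi", ("A", "B", "C", "D"))


def quad_frame(d_coords, a_coords=(0.0, 1.0, 0.0)):
    coords = np.array([a_coords, (0, 0, 0), (1, 0, 0), d_coords], dtype=float)
    return Frame(0, 0.0, ("A", "B", "C", "D"), coords)


class TestComputeDihedral:
    @pytest.mark.parametrize(
        "d_coords, expected",
        [((1.0, 1.0, 0.0), 0.0), ((1.0, -1.0, 0.0), 180.0)],
        ids=["cis", "trans"],
    )
    def test_planar_configurations(self, d_coords, expected):
        assert compute_dihedral(quad_frame(d_coords), SPEC) == pytest.approx(expected)

    @pytest.mark.parametrize("phi", [73.0, -73.0, 1.0, 120.0, -179.0, 180.0])
    def test_constructed_rotation_is_the_oracle(self, phi):
        # D built by rotating the cis position (1,1,0) about the B->C (x) axis
        # by +phi; the constructing angle defines the positive sense.
        rad = math.radians(phi)
        frame = quad_frame((1.0, math.cos(rad), math.sin(rad)))
        assert compute_dihedral(frame, SPEC) == pytest.approx(phi, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        phi = float(rng.uniform(-179, 180))
        frame = quad_frame((1.0, math.cos(math.radians(phi)), math.sin(math.radians(phi))))
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-50, 50, size=3)
        moved = Frame(0, 0.0, frame.atom_labels, frame.coordinates @ rot.T + shift)
        assert compute_dihedral(moved, SPEC) == pytest.approx(phi, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_reversing_quadruple_preserves_value(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-3, 3, size=(4, 3))
        frame = Frame(0, 0.0, ("A", "B", "C", "D"), coords)
        reverse = DihedralSpec("chi", ("D", "C", "B", "A"))
        assert compute_dihedral(frame, SPEC) == pytest.approx(
            compute_dihedral(frame, reverse), abs=1e-9
        )

    def test_missing_atom_raises(self):
        frame = quad_frame((1, 1, 0))
        with pytest.raises(UnknownAtomError, match="unknown atom 'X'"):
            compute_dihedral(frame, DihedralSpec("chi", ("A", "B", "C", "X")))

    def test_collinear_triple_raises(self):
        # A on the B-C line
        frame = quad_frame((1, 1, 0), a_coords=(-1.0, 0.0, 0.0))
        with pytest.raises(DegenerateGeometryError):
            compute_dihedral(frame, SPEC)


class TestComputeDistance:
    def test_pythagorean_triple(self):
        frame = Frame(0, 0.0, ("P", "Q"), np.array([[0, 0, 0], [3, 4, 0.0]]))
        assert compute_distance(frame, ("P", "Q")) == pytest.approx(5.0)

    def test_identical_coordinates_and_symmetry(self):
        rng = np.random.default_rng(7)
        frame = Frame(0, 0.0, ("P", "Q", "R"), rng.normal(size=(3, 3)))
        assert compute_distance(frame, ("P", "Q")) == compute_distance(frame, ("Q", "P"))
        same = Frame(0, 0.0, ("P", "Q"), np.array([[1.0, 2, 3], [1, 2, 3]]))
        assert compute_distance(same, ("P", "Q")) == 0.0

    def test_missing_label(self):
        frame = Frame(0, 0.0, ("P",), np.zeros((1, 3)))
        with pytest.raises(UnknownAtomError):
            compute_distance(frame, ("P", "Z"))


class TestSchedules:
    def test_production_run_frame_count(self):
        """A 5 ns run saved every 4 ps yields 1250 post-initial frames."""
        times = saved_frame_times(SamplingSchedule(5000, 4, include_initial=False))
        assert len(times) == 1250
        assert times[0] == 4.0 and times[-1] == 5000.0

    @pytest.mark.parametrize(
        "duration, include_initial, expected",
        [(0, False, 0), (0, True, 1), (100, False, 25), (100, True, 26)],
    )
    def test_small_schedules(self, duration, include_initial, expected):
        sched = SamplingSchedule(duration, 4, include_initial=include_initial)
        assert len(saved_frame_times(sched)) == expected

    def test_every_tenth_of_1251_frames_gives_126(self):
        assert len(decimation_indices(1251, 10, 0)) == 126
        assert len(decimation_indices(1250, 10, 0)) == 125

    def test_identity_decimation(self):
        assert decimation_indices(10, 1, 0) == list(range(10))

    @given(st.integers(0, 10_000), st.integers(1, 50), st.integers(0, 49))
    def test_length_matches_enumeration(self, n, stride, offset):
        if offset >= stride:
            offset = offset % stride
        idx = decimation_indices(n, stride, offset)
        brute = [i for i in range(n) if i >= offset and (i - offset) % stride == 0]
        assert idx == brute
        assert len(idx) == math.ceil((n - offset) / stride) if n > offset else len(idx) == 0

    @pytest.mark.parametrize("stride, offset", [(0, 0), (5, 5), (5, -1)])
    def test_invalid_arguments(self, stride, offset):
        with pytest.raises(ValueError):
            decimation_indices(10, stride, offset)


class TestAngularHistogram:
    def test_single_value_occupies_one_bin(self):
        series = AngleSeries("d", (-76.2,) * 50, tuple(range(50)))
        dist = angular_histogram(series, 1.0)
        assert np.count_nonzero(dist.densities) == 1
        assert dist.bin_centers[np.argmax(dist.densities)] == pytest.approx(-76.5)

    def test_uniform_series_gives_flat_density(self):
        values = tuple(wrap_angle(-179.5 + k) for k in range(360))
        dist = angular_histogram(AngleSeries("d", values, tuple(range(360))), 1.0)
        assert np.allclose(dist.densities, 1.0 / 360.0)

    def test_wraparound_values_fall_in_adjacent_circular_bins(self):
        series = AngleSeries("d", (179.5, -179.5), (0, 1))
        dist = angular_histogram(series, 5.0)
        occupied = np.nonzero(dist.densities)[0]
        n = len(dist.densities)
        gap = min((occupied[1] - occupied[0]) % n, (occupied[0] - occupied[1]) % n)
        assert gap <= 1

    @given(st.lists(st.floats(-179.999, 180.0), min_size=1, max_size=300))
    def test_unit_circular_integral(self, values):
        dist = angular_histogram(AngleSeries("d", tuple(values), tuple(range(len(values)))), 2.0)
        assert abs(float(np.sum(dist.densities) * dist.bin_width) - 1.0) < 1e-9

    def test_empty_series_rejected(self):
        with pytest.raises(NoDataError):
            angular_histogram(AngleSeries("d", (), ()), 1.0)

    def test_bin_width_must_divide_circle(self):
        series = AngleSeries("d", (0.0,), (0,))
        with pytest.raises(ValueError, match="divide 360"):
            angular_histogram(series, 7.0)


class TestFindModes:
    def test_single_spike(self):
        series = AngleSeries("d", (-76.0,) * 100, tuple(range(100)))
        dist = angular_histogram(series, 1.0)
        modes = find_modes(dist)
        assert len(modes) == 1
        assert modes[0].center_deg == pytest.approx(-76.5, abs=1.0)
        assert modes[0].half_width_uncertainty_deg == 0.5

    def test_uniform_density_has_no_modes(self):
        values = tuple(wrap_angle(-179.5 + k) for k in range(360))
        dist = angular_histogram(AngleSeries("d", values, tuple(range(360))), 1.0)
        assert find_modes(dist) == []

    def test_bimodal_von_mises_recovery(self):
        """Mixture centers −113° and −76° recovered within ±2° (κ=50, n=1e4)."""
        model = TorsionModel(((-113.0, 50.0, 0.5), (-76.0, 50.0, 0.5)))
        series = gen_angle_series(model, 10_000, seed=2024)
        modes = find_modes(angular_histogram(series, 1.0))
        found = sorted(m.center_deg for m in modes[:2])
        assert len(modes) >= 2
        assert abs(found[0] - (-113.0)) <= 2.0
        assert abs(found[1] - (-76.0)) <= 2.0

    def test_modes_sorted_by_density(self):
        model = TorsionModel(((-113.0, 80.0, 0.7), (60.0, 80.0, 0.3)))
        series = gen_angle_series(model, 20_000, seed=5)
        modes = find_modes(angular_histogram(series, 1.0), min_separation_deg=20)
        densities = [m.density for m in modes]
        assert densities == sorted(densities, reverse=True)
        assert abs(modes[0].center_deg - (-113.0)) <= 2.0


class TestXYZRoundTrip:
    def test_write_then_read_preserves_frames(self, tmp_path):
        rng = np.random.default_rng(3)
        frames = [
            Frame(i, 4.0 * i, ("C1", "C2", "N3"), rng.normal(size=(3, 3)))
            for i in range(4)
        ]
        path = tmp_path / "traj.xyz"
        write_xyz_frames(frames, path)
        back = read_xyz_frames(path)
        assert len(back) == 4
        for orig, rt in zip(frames, back):
            assert rt.atom_labels == orig.atom_labels
            assert rt.time_ps == pytest.approx(orig.time_ps)
            np.testing.assert_allclose(rt.coordinates, orig.coordinates, atol=1e-6)
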