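import math

import numpy as np
import pytest

from kvclamp import simulate
from kvclamp.geometry import (
    G385,
    GeometryError,
    HelixSegment,
    chain_kink_angles,
    helix_axis,
    kink_angle,
    lower_s6_segment,
    read_trajectory,
    symmetry_angles,
    trajectory_stats,
    upper_s6_segment,
    write_trajectory,
)


def rotation_matrix(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()


@pytest.fixture()
def straight_bundle():
    return simulate.make_helix_bundle(kink_deg=0.0, n_frames=1)


@pytest.fixture()
def kinked_bundle():
    return simulate.make_helix_bundle(kink_deg=25.0, n_frames=1)


class TestPdbRoundTrip:
    def test_write_read_identity_at_pdb_precision(self, tmp_path):
        traj = simulate.make_helix_bundle(kink_deg=25.0, n_frames=4, coord_noise_A=0.2, seed=9)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 4
        assert np.abs(back.coords - traj.coords).max() < 1e-3
        assert np.allclose(back.times_ns, traj.times_ns)

    def test_single_model_file(self, tmp_path):
        traj = simulate.make_helix_bundle(n_frames=1)
        path = tmp_path / "one.pdb"
        write_trajectory(traj, path)
        assert read_trajectory(path).n_frames == 1

    def test_generator_frame_times(self):
        traj = simulate.make_helix_bundle(n_frames=100, frame_dt_ns=0.1)
        assert np.allclose(traj.times_ns, np.arange(100) * 0.1)

    def test_missing_file_is_named_error(self):
        with pytest.raises(GeometryError, match="not found"):
            read_trajectory("/nonexistent/file.pdb")


class TestHelixAxis:
    def test_straight_helix_axis_is_z(self, straight_bundle):
        # subunit A is generated along -z before bundle placement
        ax, _ = helix_axis(straight_bundle.frame(0), upper_s6_segment("A"))
        assert abs(abs(ax[2]) - 1.0) < math.radians(1.0)

    def test_axis_is_rotation_equivariant(self, straight_bundle):
        fr = straight_bundle.frame(0)
        ax, _ = helix_axis(fr, upper_s6_segment("A"))
        R = rotation_matrix(np.random.default_rng(0))
        fr2 = fr.copy()
        fr2.coord = fr.coord @ R.T
        ax2, _ = helix_axis(fr2, upper_s6_segment("A"))
        assert np.degrees(np.arccos(np.clip(abs(np.dot(R @ ax, ax2)), -1, 1))) < 1.0

    def test_noisy_axis_within_2_degrees(self):
        traj = simulate.make_helix_bundle(kink_deg=0.0, n_frames=1, coord_noise_A=0.3, seed=2)
        ax, _ = helix_axis(traj.frame(0), upper_s6_segment("A"))
        tilt = np.degrees(np.arccos(np.clip(abs(ax[2]), -1, 1)))
        assert tilt < 2.0

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            HelixSegment("A", 390, 393)

    def test_missing_calpha_is_named_error(self, straight_bundle):
        fr = straight_bundle.frame(0)
        with pytest.raises(GeometryError, match="C-alpha"):
            helix_axis(fr, HelixSegment("A", 300, 320))


class TestKinkAngle:
    def test_straight_helix_has_zero_kink(self, straight_bundle):
        for c in "ABCD":
            assert kink_angle(straight_bundle.frame(0), c) < 0.5

    @pytest.mark.parametrize("kink", [10.0, 25.0, 40.0])
    def test_imposed_kink_recovered_noise_free(self, kink):
        traj = simulate.make_helix_bundle(kink_deg=kink, n_frames=1)
        for c in "ABCD":
            assert kink_angle(traj.frame(0), c) == pytest.approx(kink, abs=0.5)

    def test_imposed_kink_recovered_under_noise(self):
        traj = simulate.make_helix_bundle(kink_deg=25.0, n_frames=20, coord_noise_A=0.3, seed=4)
        angles = [kink_angle(traj.frame(i), "A") for i in range(20)]
        assert np.mean(angles) == pytest.approx(25.0, abs=2.0)

    def test_rigid_motion_invariance(self, kinked_bundle):
        fr = kinked_bundle.frame(0)
        ref = kink_angle(fr, "B")
        rng = np.random.default_rng(1)
        for _ in range(3):
            R = rotation_matrix(rng)
            fr2 = fr.copy()
            fr2.coord = fr.coord @ R.T + rng.uniform(-20, 20, 3)
            assert kink_angle(fr2, "B") == pytest.approx(ref, abs=1e-6)

    def test_overlapping_segments_rejected(self, kinked_bundle):
        with pytest.raises(GeometryError, match="disjoint"):
            kink_angle(
                kinked_bundle.frame(0),
                "A",
                upper=HelixSegment("A", 389, 406),
                lower=HelixSegment("A", 405, 417),
            )

    def test_equal_kinks_across_symmetric_bundle(self, kinked_bundle):
        kinks = chain_kink_angles(kinked_bundle.frame(0))
        assert np.ptp(kinks) < 1e-6


class TestSymmetryAngles:
    def test_c4_bundle_gives_four_right_angles(self, kinked_bundle):
        sym = symmetry_angles(kinked_bundle.frame(0))
        assert np.allclose(sym, 90.0, atol=1e-6)

    def test_radial_displacement_preserves_angle_sum(self, straight_bundle):
        fr = straight_bundle.frame(0).copy()
        mask = (fr.chain_id == "A") & (fr.res_id == G385)
        before = symmetry_angles(straight_bundle.frame(0))
        # push subunit A radially outward within the G385 plane (z fixed)
        fr.coord[mask, :2] = fr.coord[mask, :2] * 1.15
        after = symmetry_angles(fr)
        assert after.sum() == pytest.approx(360.0, abs=1e-6)
        # neighbors' angles move in the opposite direction from the displaced vertex
        assert (after[0] - before[0]) * (after[1] - before[1]) < 0

    def test_asymmetric_subunit_spreads_angles_monotonically(self):
        spreads = []
        for extra in (0.0, 3.0, 8.0):
            traj = simulate.make_helix_bundle(
                kink_deg=25.0, asym_subunit=0, asym_extra_deg=extra, n_frames=1
            )
            sym = symmetry_angles(traj.frame(0))
            spreads.append(sym.max() - sym.min())
        assert spreads[0] == pytest.approx(0.0, abs=1e-9)
        assert spreads[0] < spreads[1] < spreads[2]

    def test_rigid_motion_invariance(self, kinked_bundle):
        fr = kinked_bundle.frame(0)
        rng = np.random.default_rng(3)
        R = rotation_matrix(rng)
        fr2 = fr.copy()
        fr2.coord = fr.coord @ R.T + np.array([5.0, -2.0, 13.0])
        assert np.allclose(symmetry_angles(fr2), symmetry_angles(fr), atol=1e-6)

    def test_fewer_than_four_chains_rejected(self, kinked_bundle):
        fr = kinked_bundle.frame(0)
        sub = fr.select(fr.chain_id != "D")
        with pytest.raises(GeometryError):
            symmetry_angles(sub)


class TestTrajectoryStats:
    def test_window_sample_count(self):
        traj = simulate.make_helix_bundle(n_frames=601, frame_dt_ns=0.1)
        mean, sd, n = trajectory_stats(traj, lambda fr: kink_angle(fr, "A"), 50.0, 0.1)
        assert n == 501

    def test_constant_observable_has_zero_sd(self):
        traj = simulate.make_helix_bundle(kink_deg=25.0, n_frames=60, frame_dt_ns=0.1)
        mean, sd, _ = trajectory_stats(traj, lambda fr: kink_angle(fr, "A"), 5.0, 0.1)
        assert mean == pytest.approx(25.0, abs=0.5)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_window_longer_than_trajectory_rejected(self):
        traj = simulate.make_helix_bundle(n_frames=10, frame_dt_ns=0.1)
        with pytest.raises(GeometryError, match="window"):
            trajectory_stats(traj, lambda fr: 1.0, 50.0, 0.1)

    def test_vector_observable(self):
        traj = simulate.make_helix_bundle(kink_deg=25.0, n_frames=30, frame_dt_ns=0.1)
        mean, sd, n = trajectory_stats(traj, symmetry_angles, 2.0, 0.1)
        assert mean.shape == (4,)
        assert np.allclose(mean, 90.0, atol=1e-6)
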