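"""Marker I/O, gap interpolation, segment frames and Euler decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mtvalidate.errors import DataError, FormatError, GeometryError
from mtvalidate.kinematics import (
    MarkerFrameSequence,
    SpineModelDefinition,
    build_segment_frame,
    compute_lumbar_angles,
    euler_to_matrix,
    euler_xyz,
    interpolate_gaps,
    primary_angle,
    read_marker_tsv,
    write_marker_tsv,
)
from mtvalidate.protocol import Movement
from mtvalidate.synthetic import nominal_geometry, synthesize_marker_trajectories


@pytest.fixture
def flexion_seq():
    t = np.linspace(0, 2, 80)
    theta = 12.0 * np.sin(np.pi * t / 2) ** 2
    return synthesize_marker_trajectories(t, theta, Movement.FORWARD_FLEXION)


class TestMarkerIO:
    def test_write_read_round_trip(self, flexion_seq, tmp_path):
        p = tmp_path / "m.tsv"
        write_marker_tsv(flexion_seq, p)
        back = read_marker_tsv(p)
        assert back.labels == flexion_seq.labels
        assert np.allclose(back.data, flexion_seq.data, atol=1e-5)

    def test_empty_file_is_a_format_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_marker_tsv(p)

    def test_missing_required_marker_listed(self, flexion_seq, tmp_path):
        p = tmp_path / "m.tsv"
        write_marker_tsv(flexion_seq, p)
        with pytest.raises(FormatError, match="NOPE"):
            read_marker_tsv(p, required_labels=["NOPE"])

    def test_blank_frame_flagged_missing(self, flexion_seq, tmp_path):
        seq = flexion_seq.copy()
        seq.data[10, 0, :] = np.nan
        p = tmp_path / "m.tsv"
        write_marker_tsv(seq, p)
        back = read_marker_tsv(p)
        mask = back.missing_mask(back.labels[0])
        assert mask[10] and mask.sum() == 1

    def test_zero_triplet_is_a_gap(self, flexion_seq, tmp_path):
        seq = flexion_seq.copy()
        seq.data[5, 2, :] = 0.0
        p = tmp_path / "m.tsv"
        write_marker_tsv(seq, p)
        back = read_marker_tsv(p)
        assert back.missing_mask(back.labels[2])[5]


class TestGapInterpolation:
    def _seq_with_gap(self, traj, gap):
        t = np.arange(len(traj), dtype=float) / 179.0
        data = np.tile(traj[:, None, :], (1, 1, 1)).astype(float)
        data[gap] = np.nan
        return MarkerFrameSequence(t, ("M",), data)

    def test_linear_gap_filled_exactly(self):
        traj = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
        seq = self._seq_with_gap(traj, [10])
        out = interpolate_gaps(seq, max_gap_frames=3)
        assert out.positions("M")[10, 0] == pytest.approx(10.0, abs=1e-9)

    def test_no_gaps_is_identity(self, flexion_seq):
        out = interpolate_gaps(flexion_seq)
        assert np.array_equal(out.data, flexion_seq.data)

    def test_sinusoid_gap_error_small_at_mocap_rate(self):
        t = np.arange(200) / 179.0
        traj = np.column_stack([50 * np.sin(2 * np.pi * 1.0 * t),
                                np.zeros_like(t), np.zeros_like(t)])
        seq = self._seq_with_gap(traj, [100, 101, 102])
        out = interpolate_gaps(seq, max_gap_frames=3)
        err = np.abs(out.positions("M")[100:103, 0] - traj[100:103, 0])
        assert err.max() < 0.1

    def test_long_gap_names_marker_and_span(self):
        traj = np.column_stack([np.arange(30.0), np.zeros(30), np.zeros(30)])
        seq = self._seq_with_gap(traj, list(range(10, 18)))
        with pytest.raises(DataError, match=r"M.*8 frames"):
            interpolate_gaps(seq, max_gap_frames=3)


class TestSegmentFrames:
    def test_nominal_pose_gives_identity(self):
        geom = nominal_geometry()
        model = SpineModelDefinition()
        for seg in (model.upper, model.lower, model.pelvis):
            frame = build_segment_frame(geom, seg)
            assert np.allclose(frame.rotation, np.eye(3), atol=1e-12)

    def test_rigid_rotation_recovered(self, rng):
        geom = nominal_geometry()
        model = SpineModelDefinition()
        Q = Rotation.from_rotvec(np.deg2rad(25) * np.array([0.2, 0.5, -0.3])
                                 / np.linalg.norm([0.2, 0.5, -0.3])).as_matrix()
        rotated = {k: Q @ v for k, v in geom.items()}
        frame = build_segment_frame(rotated, model.upper)
        assert np.max(np.abs(frame.rotation - Q)) < 1e-9

    def test_swapped_lateral_markers_detected(self):
        geom = nominal_geometry()
        geom["L1_left"], geom["L1_right"] = geom["L1_right"], geom["L1_left"]
        with pytest.raises(GeometryError, match="swapped"):
            build_segment_frame(geom, SpineModelDefinition().upper)

    def test_collinear_markers_rejected(self):
        geom = nominal_geometry()
        geom["L3_spinous"] = 0.5 * (geom["L1_left"] + geom["L1_right"])
        with pytest.raises(GeometryError, match="collinear"):
            build_segment_frame(geom, SpineModelDefinition().upper)


class TestEulerXYZ:
    def test_identity_and_single_axis(self):
        ang, gim = euler_xyz(np.eye(3))
        assert np.allclose(ang, 0.0) and not gim
        R = euler_to_matrix([30.0, 0.0, 0.0])
        ang, _ = euler_xyz(R)
        assert ang == pytest.approx([30.0, 0.0, 0.0], abs=1e-12)

    @staticmethod
    def _random_rotations(rng, n):
        q = rng.normal(size=(n, 4))
        return Rotation.from_quat(q / np.linalg.norm(q, axis=1, keepdims=True))

    def test_decompose_compose_round_trip(self, rng):
        R = self._random_rotations(rng, 500).as_matrix()
        ang, _ = euler_xyz(R)
        assert np.max(np.abs(euler_to_matrix(ang) - R)) < 1e-9

    def test_agrees_with_scipy_intrinsic_xyz(self, rng):
        R = self._random_rotations(rng, 200).as_matrix()
        ours, _ = euler_xyz(R)
        ref = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
        assert np.allclose(ours, ref, atol=1e-9)

    def test_non_rotation_rejected(self):
        with pytest.raises(GeometryError):
            euler_xyz(np.diag([1.0, 1.0, -1.0]))
        with pytest.raises(GeometryError):
            euler_xyz(2.0 * np.eye(3))


class TestLumbarAngles:
    def test_neutral_standing_all_zero(self):
        t = np.linspace(0, 1, 10)
        seq = synthesize_marker_trajectories(t, np.zeros_like(t),
                                             Movement.EXTENSION)
        kas = compute_lumbar_angles(seq)
        assert np.allclose(kas.upper_xyz, 0.0, atol=1e-9)
        assert np.allclose(kas.lower_xyz, 0.0, atol=1e-9)

    def test_flexion_loads_only_x_component(self, flexion_seq):
        kas = compute_lumbar_angles(flexion_seq)
        assert np.abs(kas.upper_xyz[:, 0]).max() > 5.0
        assert np.abs(kas.upper_xyz[:, 1:]).max() < 1e-9

    def test_left_lateral_bend_sign_convention(self):
        t = np.linspace(0, 2, 60)
        theta = 15.0 * np.sin(np.pi * t / 2) ** 2
        seq = synthesize_marker_trajectories(t, theta, Movement.LEFT_LATERAL_BEND)
        kas = compute_lumbar_angles(seq)
        z, meta = primary_angle(kas, Movement.LEFT_LATERAL_BEND, "upper_lumbar")
        assert meta["component"] == "z"
        assert z.min() < -7.0 and np.abs(kas.upper_xyz[:, 0]).max() < 1e-9

    def test_angles_invariant_to_lab_frame_rotation(self, flexion_seq, rng):
        kas0 = compute_lumbar_angles(flexion_seq)
        Q = Rotation.from_euler("XYZ", [8.0, -12.0, 5.0], degrees=True).as_matrix()
        rotated = flexion_seq.copy()
        rotated.data = np.einsum("ij,nmj->nmi", Q, rotated.data)
        kas1 = compute_lumbar_angles(rotated)
        assert np.max(np.abs(kas1.upper_xyz - kas0.upper_xyz)) < 1e-9
        assert np.max(np.abs(kas1.lower_xyz - kas0.lower_xyz)) < 1e-9
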