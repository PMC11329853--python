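"""Synthetic-data generator: profiles, rigid marker motion, sensor physics."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mtvalidate.sensor as sensor
from mtvalidate.errors import ParameterError, SimulationError
from mtvalidate.kinematics import compute_lumbar_angles
from mtvalidate.protocol import Movement, MovementProtocolEntry, default_protocol
from mtvalidate.synthetic import (
    LOWER_MARKERS,
    PELVIS_MARKERS,
    UPPER_MARKERS,
    ScenarioConfig,
    SensorPhysics,
    generate_angle_profile,
    generate_scenario,
    nominal_geometry,
    simulate_sensor_log,
    synthesize_marker_trajectories,
)


def rep_peaks(entry, t, theta, rep_duration=4.0, rest=1.0):
    """Peak angle within each repetition window."""
    peaks = []
    for j in range(entry.repetitions):
        t0 = rest + j * (rep_duration + rest)
        win = (t >= t0) & (t <= t0 + rep_duration)
        peaks.append(theta[win].max())
    return np.array(peaks)


class TestAngleProfile:
    def test_single_rep_peak_equals_amplitude(self):
        entry = MovementProtocolEntry(movement=Movement.EXTENSION, repetitions=1,
                                      amplitude_fractions=(1.0,), end_range_deg=30.0)
        t, theta = generate_angle_profile(entry, rate_hz=100.0)
        assert theta.max() == pytest.approx(30.0, abs=1e-9)

    def test_flexion_peaks_follow_protocol(self, flexion_entry):
        t, theta = generate_angle_profile(flexion_entry, rate_hz=179.0)
        peaks = rep_peaks(flexion_entry, t, theta)
        assert peaks == pytest.approx([20.0, 20.0, 40.0], abs=1e-6)

    def test_profile_starts_and_ends_at_zero(self):
        for entry in default_protocol():
            t, theta = generate_angle_profile(entry, rate_hz=179.0)
            assert theta[0] == 0.0 and theta[-1] == 0.0

    def test_profile_is_smooth(self, flexion_entry):
        # C1: numerical derivative has no jumps larger than curvature allows
        t, theta = generate_angle_profile(flexion_entry, rate_hz=179.0)
        d2 = np.diff(theta, 2) * 179.0**2
        assert np.abs(d2).max() < 2.0 * 40.0 * (2 * np.pi / 4.0) ** 2

    @pytest.mark.parametrize("rate,dur", [(0.0, 4.0), (-5.0, 4.0), (100.0, 0.0)])
    def test_invalid_parameters_rejected(self, flexion_entry, rate, dur):
        with pytest.raises(ParameterError):
            generate_angle_profile(flexion_entry, rate_hz=rate, rep_duration_s=dur)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(fracs=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
           end_range=st.floats(5.0, 60.0))
    def test_peak_heights_match_protocol_for_any_entry(self, fracs, end_range):
        entry = MovementProtocolEntry(
            movement=Movement.EXTENSION, repetitions=len(fracs),
            amplitude_fractions=tuple(fracs), end_range_deg=end_range)
        t, theta = generate_angle_profile(entry, rate_hz=100.0)
        peaks = rep_peaks(entry, t, theta)
        assert peaks == pytest.approx([f * end_range for f in fracs], abs=1e-9)
        assert theta[0] == 0.0 and theta[-1] == 0.0


class TestMarkerForwardModel:
    def test_zero_angle_series_keeps_nominal_geometry(self):
        t = np.linspace(0, 1, 50)
        seq = synthesize_marker_trajectories(t, np.zeros_like(t),
                                             Movement.FORWARD_FLEXION)
        geom = nominal_geometry()
        for lab in seq.labels:
            assert np.allclose(seq.positions(lab), geom[lab][None, :])

    def test_round_trip_recovers_shared_angles(self):
        t = np.linspace(0, 2, 100)
        theta = 10.0 * np.sin(np.pi * t / 2) ** 2
        seq = synthesize_marker_trajectories(t, theta, Movement.FORWARD_FLEXION,
                                             shares=(0.5, 0.5))
        kas = compute_lumbar_angles(seq, lowpass_cutoff_hz=None)
        # flexion is convention-negative about the ML axis
        assert np.max(np.abs(kas.upper_xyz[:, 0] + 0.5 * theta)) < 1e-6
        assert np.max(np.abs(kas.lower_xyz[:, 0] + 0.5 * theta)) < 1e-6

    def test_within_segment_distances_are_rigid(self):
        entry = default_protocol()[2]  # left lateral bend
        t, theta = generate_angle_profile(entry, rate_hz=60.0)
        seq = synthesize_marker_trajectories(t, theta, entry.movement)
        for group in (UPPER_MARKERS, LOWER_MARKERS, PELVIS_MARKERS):
            pts = np.stack([seq.positions(lab) for lab in group], axis=1)
            d01 = np.linalg.norm(pts[:, 0] - pts[:, -1], axis=1)
            assert np.ptp(d01) < 1e-9


class TestSensorSimulation:
    def test_constant_strain_follows_gauge_equation(self, tmp_path):
        # dR/R = K eps: eps=0.01, K=1, R0=1000 -> R = 1010 ohm at every sample
        phys = SensorPhysics.ideal(baseline_resistance_ohm=1000.0, gauge_factor=1.0)
        t = np.arange(100) / 50.0
        log = simulate_sensor_log(t, np.full(100, 0.01), phys, trial_index=0)
        assert np.all(log.counts == 10100)
        p = tmp_path / "log.csv"
        p.write_text(log.to_text())
        rs = sensor.decode_log(p)
        assert np.all(rs.r == 1010.0)

    def test_saturation_clips_resistance(self):
        phys = SensorPhysics.ideal(baseline_resistance_ohm=1000.0,
                                   gauge_factor=1.0, saturation_strain=0.05)
        t = np.arange(200) / 50.0
        eps = np.linspace(0, 0.10, 200)
        log = simulate_sensor_log(t, eps, phys, trial_index=0)
        assert log.counts.max() == round(1000.0 * 1.05 / 0.1)
        assert np.sum(log.counts == log.counts.max()) > 50  # plateau, not a peak

    def test_rebound_transient_matches_stated_formula(self):
        phys = SensorPhysics.ideal(
            baseline_resistance_ohm=1000.0, gauge_factor=10.0,
            rebound_amplitude=0.02, rebound_tau_s=0.5,
            rebound_trigger_strain=0.005)
        rate = 100.0
        t = np.arange(400) / rate
        eps = np.zeros_like(t)
        eps[50:150] = -0.03  # compression pulse, then release
        log = simulate_sensor_log(t, eps, phys, trial_index=0)
        # independent evaluation of the stated model
        i_rel = 150  # first sample back above the trigger
        expected_eps = eps.copy()
        expected_eps[i_rel:] += 0.02 * np.exp(-(t[i_rel:] - t[i_rel]) / 0.5)
        expected_counts = np.rint(1000.0 * (1 + 10.0 * expected_eps) / 0.1)
        assert np.array_equal(log.counts, expected_counts)
        # post-release resistance transiently exceeds baseline
        assert log.counts[i_rel] > round(1000.0 / 0.1)

    def test_fatigue_raises_baseline_across_trials(self):
        phys = SensorPhysics.ideal(fatigue_drift_per_trial=0.01)
        t = np.arange(50) / 50.0
        r_first = simulate_sensor_log(t, np.zeros_like(t), phys, 0).counts[0]
        r_late = simulate_sensor_log(t, np.zeros_like(t), phys, 5).counts[0]
        assert r_late == pytest.approx(r_first * 1.05, rel=1e-6)

    def test_impossible_physics_raises(self):
        phys = SensorPhysics(noise_sd=1e6, spike_rate=0.0)
        t = np.arange(500) / 50.0
        with pytest.raises(SimulationError):
            simulate_sensor_log(t, np.zeros_like(t), phys, 0, seed=1)


def _tree_hash(root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(root.rglob("*")) if p.is_file()}


class TestScenario:
    def test_counts_and_byte_determinism(self, tmp_path):
        cfg = ScenarioConfig(n_participants=1, seed=7)
        m1 = generate_scenario(cfg, tmp_path / "a")
        generate_scenario(cfg, tmp_path / "b")
        trials = m1["participants"][0]["trials"]
        assert len(trials) == 6
        assert sum(len(tr["sensor_logs"]) for tr in trials) == 36
        assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")

    def test_seed_changes_noise_but_not_profile_peaks(self, tmp_path):
        base = dict(n_participants=1, marker_noise_mm=0.2)
        m1 = generate_scenario(ScenarioConfig(seed=1, **base), tmp_path / "s1")
        m2 = generate_scenario(ScenarioConfig(seed=2, **base), tmp_path / "s2")
        tr1 = m1["participants"][0]["trials"][0]
        tr2 = m2["participants"][0]["trials"][0]
        log1 = (tmp_path / "s1" / tr1["sensor_logs"]["1"]).read_bytes()
        log2 = (tmp_path / "s2" / tr2["sensor_logs"]["1"]).read_bytes()
        assert log1 != log2
        from mtvalidate.kinematics import read_marker_tsv
        for sdir, tr in ((tmp_path / "s1", tr1), (tmp_path / "s2", tr2)):
            seq = read_marker_tsv(sdir / tr["marker_file"])
            kas = compute_lumbar_angles(seq)
            peak = np.abs(kas.upper_xyz[:, 0]).max() + np.abs(
                kas.lower_xyz[:, 0]).max()
            # flexion entry: 50 deg end range at 100%, split 50/50
            assert peak == pytest.approx(50.0, abs=0.5)
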