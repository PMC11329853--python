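"""Synthetic study generator: movements, marker trajectories, sensor logs.

This module simulates the complete measurement setup the analysis pipeline
expects, so the pipeline can be exercised end to end without access to the
original laboratory recordings:

* **reference angle profiles** — one smooth raised-cosine excursion per
  repetition of a movement protocol entry, separated by rest periods;
* **marker trajectories** — a rigid three-segment forward model (pelvis
  fixed; lower lumbar rotated against the pelvis and upper lumbar against
  the lower lumbar by configurable shares of the reference angle) driving
  the full marker set, written as Qualisys-style TSV;
* **sensor logs** — piezoresistive tape resistance R = R0 (1 + K eps) with
  configurable noise, outlier spikes, saturation clipping, per-trial
  fatigue drift of the baseline, and an exponential rebound transient after
  compression release, quantized to integer counts and hex-encoded in the
  raw log dialect.

The forward model is the exact inverse of the kinematics module on
noiseless input, which the test suite exploits for round-trip checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, ParameterError, SimulationError
from .kinematics import MarkerFrameSequence, write_marker_tsv
from .protocol import (
    MOVEMENT_AXIS_SIGN,
    MOVEMENT_PRIMARY_COMPONENT,
    Movement,
    MovementProtocolEntry,
    default_protocol,
)
from .sensor import COUNT_OHMS

__all__ = [
    "SensorPhysics",
    "StrainGainMap",
    "ScenarioConfig",
    "SensorLog",
    "nominal_geometry",
    "generate_angle_profile",
    "angle_profile_at",
    "synthesize_marker_trajectories",
    "simulate_sensor_log",
    "generate_scenario",
]

SENSOR_IDS = (1, 2, 3, 4, 5, 6)

#: Sensors on the subject's left (odd) and right (even) side of the spine,
#: rows top to bottom: (1, 2) upper, (3, 4) middle, (5, 6) lower.
LEFT_SENSORS = (1, 3, 5)


# ---------------------------------------------------------------------------
# Configuration models
# ---------------------------------------------------------------------------

class SensorPhysics(BaseModel):
    """Piezoresistive tape physics and failure-mode parameters.

    Defaults describe a plausible mid-life tape: ~1 kOhm baseline, gauge
    factor 25 (graphene-nanosheet films span roughly 10-100), ~1 Ohm RMS
    electrical noise, rare large spikes, saturation at 2.5% strain, 0.2%
    baseline growth per completed trial, and a small compression-release
    rebound with a 1 s decay.  Use :meth:`ideal` for a noise- and
    artifact-free sensor.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    baseline_resistance_ohm: float = 1000.0
    gauge_factor: float = 25.0
    noise_sd: float = 1.0
    spike_rate: float = 0.005
    spike_magnitude_mad: float = 10.0
    saturation_strain: float = 0.025
    fatigue_drift_per_trial: float = 0.002
    rebound_amplitude: float = 0.004
    rebound_tau_s: float = 1.0
    rebound_trigger_strain: float = 0.004

    @model_validator(mode="after")
    def _check(self) -> "SensorPhysics":
        if not self.baseline_resistance_ohm > 0:
            raise ParameterError("baseline_resistance_ohm must be > 0")
        if not self.gauge_factor > 0:
            raise ParameterError("gauge_factor must be > 0")
        for name in ("noise_sd", "spike_rate", "spike_magnitude_mad",
                     "saturation_strain", "fatigue_drift_per_trial",
                     "rebound_amplitude", "rebound_tau_s",
                     "rebound_trigger_strain"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        return self

    @classmethod
    def ideal(cls, **overrides) -> "SensorPhysics":
        """An artifact-free sensor: no noise, spikes, saturation, fatigue
        or rebound."""
        params = dict(noise_sd=0.0, spike_rate=0.0, spike_magnitude_mad=0.0,
                      saturation_strain=math.inf, fatigue_drift_per_trial=0.0,
                      rebound_amplitude=0.0)
        params.update(overrides)
        return cls(**params)


class StrainGainMap(BaseModel):
    """Signed gain mapping reference angle to true skin strain per sensor.

    ``gains[movement][sensor_id]`` scales the movement's reference angle
    (normalized by end range) to skin strain; positive gain = tension,
    negative = compression.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    gains: dict[Movement, dict[int, float]]

    @model_validator(mode="after")
    def _check(self) -> "StrainGainMap":
        for mv, per_sensor in self.gains.items():
            for sid, g in per_sensor.items():
                if sid not in SENSOR_IDS:
                    raise ConfigurationError(f"unknown sensor id {sid} for {mv}")
                if not math.isfinite(g):
                    raise ConfigurationError(f"non-finite gain for sensor {sid}, {mv}")
        return self

    def gain(self, sensor_id: int, movement: Movement) -> float:
        try:
            return self.gains[Movement(movement)][sensor_id]
        except KeyError:
            raise ConfigurationError(
                f"no gain configured for sensor {sensor_id}, {movement}") from None

    @classmethod
    def default(cls) -> "StrainGainMap":
        """Tension/compression pattern observed across the sensor matrix.

        Flexion stretches all tapes (tension); extension compresses all;
        lateral bending stretches the contralateral column and compresses
        the ipsilateral one; rotation stretches both upper tapes and the
        ipsilateral middle/lower tapes while mildly compressing their
        contralateral counterparts.
        """
        g = {
            Movement.FORWARD_FLEXION: {1: 0.020, 2: 0.020, 3: 0.025,
                                       4: 0.025, 5: 0.030, 6: 0.030},
            Movement.EXTENSION: {s: -0.015 for s in SENSOR_IDS},
            Movement.LEFT_LATERAL_BEND: {1: -0.012, 2: 0.020, 3: -0.012,
                                         4: 0.020, 5: -0.012, 6: 0.020},
            Movement.RIGHT_LATERAL_BEND: {1: 0.020, 2: -0.012, 3: 0.020,
                                          4: -0.012, 5: 0.020, 6: -0.012},
            Movement.LEFT_ROTATION: {1: 0.015, 2: 0.015, 3: 0.015,
                                     4: -0.008, 5: 0.010, 6: -0.006},
            Movement.RIGHT_ROTATION: {1: 0.015, 2: 0.015, 3: -0.008,
                                      4: 0.015, 5: -0.006, 6: 0.010},
        }
        return cls(gains=g)


class ScenarioConfig(BaseModel):
    """Full synthetic study configuration.

    Defaults reproduce the study conditions: 10 participants, the six-block
    movement protocol, 179 Hz motion capture, and a 0.5 s sensor stream
    start offset.  The sensor sampling rate (50 Hz) and repetition timing
    (4 s per repetition, 1 s rest) are documented package defaults.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_participants: int = 10
    protocol: tuple[MovementProtocolEntry, ...] = Field(
        default_factory=lambda: tuple(default_protocol()))
    physics: SensorPhysics = Field(default_factory=SensorPhysics)
    gain_map: StrainGainMap = Field(default_factory=StrainGainMap.default)
    mocap_rate_hz: float = 179.0
    sensor_rate_hz: float = 50.0
    seed: int = 0
    stream_offset_s: float = 0.5
    rep_duration_s: float = 4.0
    rest_s: float = 1.0
    shares: tuple[float, float] = (0.5, 0.5)
    marker_noise_mm: float = 0.3

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if not (self.mocap_rate_hz > 0 and self.sensor_rate_hz > 0):
            raise ParameterError("sampling rates must be > 0")
        if self.rep_duration_s <= 0 or self.rest_s < 0:
            raise ParameterError("rep_duration_s must be > 0 and rest_s >= 0")
        if any(s < 0 for s in self.shares):
            raise ParameterError("angle shares must be >= 0")
        if self.marker_noise_mm < 0 or self.stream_offset_s < 0:
            raise ParameterError("marker_noise_mm and stream_offset_s must be >= 0")
        return self


# ---------------------------------------------------------------------------
# Reference angle profiles
# ---------------------------------------------------------------------------

def trial_duration(entry: MovementProtocolEntry, rep_duration_s: float,
                   rest_s: float) -> float:
    """Total trial length: leading rest, then one repetition + rest each."""
    return rest_s + entry.repetitions * (rep_duration_s + rest_s)


def angle_profile_at(entry: MovementProtocolEntry, times: np.ndarray,
                     rep_duration_s: float = 4.0, rest_s: float = 1.0,
                     ) -> np.ndarray:
    """Evaluate the reference angle profile (degrees) at arbitrary times.

    Each repetition j contributes a raised-cosine excursion
    ``A_j/2 * (1 - cos(2 pi (t - t0)/T))`` of peak
    ``A_j = amplitude_fraction[j] * end_range_deg`` over its window, zero
    elsewhere; the profile and its first derivative vanish at every window
    boundary (C1).
    """
    if rep_duration_s <= 0:
        raise ParameterError("rep_duration_s must be > 0")
    times = np.asarray(times, dtype=float)
    theta = np.zeros_like(times)
    for j, frac in enumerate(entry.amplitude_fractions):
        t0 = rest_s + j * (rep_duration_s + rest_s)
        inside = (times >= t0) & (times <= t0 + rep_duration_s)
        peak = frac * entry.end_range_deg
        theta[inside] = 0.5 * peak * (
            1.0 - np.cos(2.0 * np.pi * (times[inside] - t0) / rep_duration_s))
    return theta


def generate_angle_profile(entry: MovementProtocolEntry, rate_hz: float,
                           rep_duration_s: float = 4.0, rest_s: float = 1.0,
                           seed: int | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Sample a movement's reference angle profile on a uniform grid.

    Returns ``(t, theta_deg)``.  The profile is fully deterministic; the
    seed argument is accepted for interface symmetry with the stochastic
    generators but does not influence the output (repetition peaks are a
    protocol property, not a noise realization).
    """
    if rate_hz <= 0:
        raise ParameterError("rate_hz must be > 0")
    total = trial_duration(entry, rep_duration_s, rest_s)
    n = int(round(total * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    return t, angle_profile_at(entry, t, rep_duration_s, rest_s)


# ---------------------------------------------------------------------------
# Marker forward model
# ---------------------------------------------------------------------------

def nominal_geometry() -> dict[str, np.ndarray]:
    """Nominal neutral-pose marker positions, mm.

    Lab frame: X = subject-right, Y = up, Z = posterior; origin on the lab
    floor below the spine, with the L5 spinous process 1 m up.  Vertebral
    levels are spaced 40 mm apart; the lateral
    L1/L4 markers sit 40 mm off midline (~4 cm lateral to the spinal
    column).  The arrangement places each segment's midline SI reference
    directly below (lumbar) or above (pelvic crest midpoint) its origin, so
    every constructed segment frame is the identity at neutral.
    """
    g = {
        "T12_spinous": (0.0, 1200.0, 0.0),
        "L1_spinous": (0.0, 1160.0, 0.0),
        "L2_spinous": (0.0, 1120.0, 0.0),
        "L3_spinous": (0.0, 1080.0, 0.0),
        "L4_spinous": (0.0, 1040.0, 0.0),
        "L5_spinous": (0.0, 1000.0, 0.0),
        "L1_left": (-40.0, 1160.0, 0.0),
        "L1_right": (40.0, 1160.0, 0.0),
        "L4_left": (-40.0, 1040.0, 0.0),
        "L4_right": (40.0, 1040.0, 0.0),
        "PSIS_left": (-35.0, 970.0, 0.0),
        "PSIS_right": (35.0, 970.0, 0.0),
        "ASIS_left": (-120.0, 980.0, -150.0),
        "ASIS_right": (120.0, 980.0, -150.0),
        "postpel_left": (-60.0, 940.0, 20.0),
        "postpel_right": (60.0, 940.0, 20.0),
        "crest_left": (-130.0, 1020.0, 0.0),
        "crest_right": (130.0, 1020.0, 0.0),
    }
    return {k: np.array(v) for k, v in g.items()}


#: Segment membership of markers in the forward model.
UPPER_MARKERS = ("T12_spinous", "L1_spinous", "L1_left", "L1_right",
                 "L2_spinous", "L3_spinous")
LOWER_MARKERS = ("L4_spinous", "L4_left", "L4_right", "L5_spinous")
PELVIS_MARKERS = ("PSIS_left", "PSIS_right", "ASIS_left", "ASIS_right",
                  "postpel_left", "postpel_right", "crest_left", "crest_right")


def movement_axis(movement: Movement) -> np.ndarray:
    """Signed lab-frame rotation axis of a movement's primary plane."""
    mv = Movement(movement)
    axis = np.zeros(3)
    axis[MOVEMENT_PRIMARY_COMPONENT[mv]] = MOVEMENT_AXIS_SIGN[mv]
    return axis


def synthesize_marker_trajectories(t: np.ndarray, theta_deg: np.ndarray,
                                   movement: Movement,
                                   geometry: dict[str, np.ndarray] | None = None,
                                   shares: tuple[float, float] = (0.5, 0.5),
                                   marker_noise_mm: float = 0.0,
                                   rng: np.random.Generator | None = None,
                                   ) -> MarkerFrameSequence:
    """Rigid-segment forward model from a reference angle series to markers.

    The pelvis stays fixed; the lower lumbar segment rotates against the
    pelvis by ``shares[0] * theta`` and the upper lumbar against the lower
    by ``shares[1] * theta``, each about the movement's signed anatomical
    axis, pivoting at the L5 and L3 spinous processes respectively.  At
    zero angle all markers sit at their nominal positions.

    ``marker_noise_mm`` is the RMS displacement magnitude of isotropic
    Gaussian marker jitter (per-coordinate sigma = noise / sqrt(3)).
    """
    geometry = geometry if geometry is not None else nominal_geometry()
    for label in UPPER_MARKERS + LOWER_MARKERS + PELVIS_MARKERS:
        if label not in geometry:
            raise ConfigurationError(f"geometry lacks marker {label!r}")
    t = np.asarray(t, dtype=float)
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    if theta.shape != t.shape:
        raise ParameterError("t and theta_deg must have matching shapes")
    axis = movement_axis(movement)
    R_low = Rotation.from_rotvec(np.outer(shares[0] * theta, axis)).as_matrix()
    R_ur = Rotation.from_rotvec(np.outer(shares[1] * theta, axis)).as_matrix()
    c_low = geometry["L5_spinous"]
    c_up = geometry["L3_spinous"]

    labels = tuple(UPPER_MARKERS + LOWER_MARKERS + PELVIS_MARKERS)
    n = t.size
    data = np.empty((n, len(labels), 3))
    for j, lab in enumerate(labels):
        p = geometry[lab]
        if lab in PELVIS_MARKERS:
            data[:, j, :] = p
        elif lab in LOWER_MARKERS:
            data[:, j, :] = c_low + np.einsum("nik,k->ni", R_low, p - c_low)
        else:  # upper: rotate about c_up within the lower segment, then with it
            q = c_up + np.einsum("nik,k->ni", R_ur, p - c_up)
            data[:, j, :] = c_low + np.einsum("nik,nk->ni", R_low, q - c_low)
    if marker_noise_mm > 0:
        if rng is None:
            rng = np.random.default_rng()
        data = data + rng.normal(0.0, marker_noise_mm / math.sqrt(3.0), data.shape)
    return MarkerFrameSequence(t=t, labels=labels, data=data)


# ---------------------------------------------------------------------------
# Sensor simulation
# ---------------------------------------------------------------------------

@dataclass
class SensorLog:
    """A raw sensor log: quantized resistance counts plus timing metadata."""

    sensor_id: int
    trial_id: str
    start_time: datetime
    rate_hz: float
    counts: np.ndarray

    def timestamps(self) -> list[datetime]:
        return [self.start_time + timedelta(seconds=i / self.rate_hz)
                for i in range(self.counts.size)]

    def to_text(self) -> str:
        """Render the log dialect: 3 comment header lines, then
        ``timestamp_iso8601,hex_resistance`` rows."""
        lines = [
            f"# sensor_id: {self.sensor_id}",
            f"# trial_id: {self.trial_id}",
            f"# start: {self.start_time.isoformat()}",
        ]
        for ts, c in zip(self.timestamps(), self.counts):
            lines.append(f"{ts.isoformat()},{int(c):X}")
        return "\n".join(lines) + "\n"


def _rebound_transient(t: np.ndarray, eps: np.ndarray,
                       physics: SensorPhysics) -> np.ndarray:
    """Additive strain-equivalent rebound after each compression release.

    A release event is a sample where strain crosses from below the
    trigger threshold (-rebound_trigger_strain) back toward zero; each
    event adds ``amplitude * exp(-dt / tau)`` from that sample on.
    """
    extra = np.zeros_like(eps)
    if physics.rebound_amplitude <= 0:
        return extra
    trig = -physics.rebound_trigger_strain
    below = eps < trig
    events = np.flatnonzero(below[:-1] & ~below[1:]) + 1
    tau = max(physics.rebound_tau_s, 1e-12)
    for i in events:
        dt = t[i:] - t[i]
        extra[i:] += physics.rebound_amplitude * np.exp(-dt / tau)
    return extra


def simulate_sensor_log(t: np.ndarray, eps_true: np.ndarray,
                        physics: SensorPhysics, trial_index: int,
                        seed: int | np.random.Generator | None = 0,
                        sensor_id: int = 1, trial_id: str = "trial",
                        start_time: datetime | None = None,
                        rate_hz: float | None = None) -> SensorLog:
    """Forward-simulate a raw resistance log from a true strain series.

    The measured resistance is::

        R(t) = R0 (1 + d j) (1 + K eps_eff(t)) + noise + spikes

    with trial index ``j``, fatigue drift ``d`` per completed trial, and
    effective strain ``eps_eff`` equal to the true strain clipped at
    +/- saturation_strain plus the compression-release rebound transient.
    Noise is white Gaussian on resistance; spikes occur independently per
    sample with probability ``spike_rate`` and magnitude
    ``spike_magnitude_mad`` robust-scale units (1.4826 MAD of the clean
    resistance).  Spikes are positive, emulating momentary contact-loss
    transients, which spike resistance high.  The result is quantized to
    integer counts of 0.1 Ohm before hex encoding.

    Raises :class:`SimulationError` if any simulated resistance falls to
    zero or below (inconsistent physics parameters).
    """
    if trial_index < 0:
        raise ParameterError("trial_index must be >= 0")
    t = np.asarray(t, dtype=float)
    eps_true = np.asarray(eps_true, dtype=float)
    if not np.all(np.isfinite(eps_true)):
        raise ParameterError("strain series must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sat = physics.saturation_strain
    eps_eff = np.clip(eps_true, -sat, sat) if np.isfinite(sat) else eps_true.copy()
    eps_eff = eps_eff + _rebound_transient(t, eps_true, physics)

    r0 = physics.baseline_resistance_ohm * (
        1.0 + physics.fatigue_drift_per_trial * trial_index)
    r_clean = r0 * (1.0 + physics.gauge_factor * eps_eff)

    # draws are unconditional so that scaling noise_sd rescales the same
    # realization instead of shifting the generator state
    noise = physics.noise_sd * rng.standard_normal(t.size)
    u = rng.random(t.size)
    med = np.median(r_clean)
    mad_scale = 1.4826 * np.median(np.abs(r_clean - med))
    if mad_scale <= 0:
        mad_scale = max(physics.noise_sd, 1.0)
    spikes = np.where(u < physics.spike_rate,
                      physics.spike_magnitude_mad * mad_scale, 0.0)

    r = r_clean + noise + spikes
    counts = np.rint(r / COUNT_OHMS).astype(np.int64)
    if np.any(counts <= 0):
        raise SimulationError(
            "simulated resistance is non-positive; physics parameters are "
            "inconsistent (noise/spikes too large for the baseline?)")
    if rate_hz is None:
        rate_hz = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    return SensorLog(sensor_id=sensor_id, trial_id=trial_id,
                     start_time=start_time or datetime(2026, 1, 1, 9, 0, 0),
                     rate_hz=float(rate_hz), counts=counts)


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

def _participant_id(i: int) -> str:
    return f"P{i + 1:02d}"


def generate_scenario(config: ScenarioConfig, out_dir) -> dict:
    """Generate a full on-disk synthetic dataset and its manifest.

    Writes one marker TSV and six sensor logs per participant x protocol
    entry under ``out_dir`` and a ``manifest.json`` mapping each trial to
    its files, movement, and stream start timestamps (the sensor stream
    starts ``stream_offset_s`` after motion capture).  Bit-identical across
    runs with the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = datetime(2026, 1, 5, 9, 0, 0)
    manifest: dict = {
        "scenario": json.loads(config.model_dump_json()),
        "participants": [],
    }
    for p_idx in range(config.n_participants):
        pid = _participant_id(p_idx)
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        trials = []
        for t_idx, entry in enumerate(config.protocol):
            mv = entry.movement
            trial_id = f"{pid}_{mv.value}_t{t_idx}"
            mocap_start = base + timedelta(hours=p_idx, minutes=5 * t_idx)
            sensor_start = mocap_start + timedelta(seconds=config.stream_offset_s)

            t_m, theta = generate_angle_profile(
                entry, config.mocap_rate_hz, config.rep_duration_s, config.rest_s)
            marker_rng = np.random.default_rng(
                [config.seed & 0x7FFFFFFF, p_idx, t_idx, 997])
            seq = synthesize_marker_trajectories(
                t_m, theta, mv, shares=config.shares,
                marker_noise_mm=config.marker_noise_mm, rng=marker_rng)
            marker_file = pdir / f"{trial_id}_markers.tsv"
            write_marker_tsv(seq, marker_file)

            total = t_m[-1]
            n_s = int(math.floor((total - config.stream_offset_s)
                                 * config.sensor_rate_hz)) + 1
            ts_rel = config.stream_offset_s + np.arange(n_s) / config.sensor_rate_hz
            prof = angle_profile_at(entry, ts_rel, config.rep_duration_s,
                                    config.rest_s)
            logs = {}
            for sid in SENSOR_IDS:
                gain = config.gain_map.gain(sid, mv)
                eps_true = gain * prof / entry.end_range_deg
                sensor_rng = np.random.default_rng(
                    [config.seed & 0x7FFFFFFF, p_idx, t_idx, sid])
                log = simulate_sensor_log(
                    ts_rel - config.stream_offset_s, eps_true, config.physics,
                    trial_index=t_idx, seed=sensor_rng, sensor_id=sid,
                    trial_id=trial_id, start_time=sensor_start,
                    rate_hz=config.sensor_rate_hz)
                log_file = pdir / f"{trial_id}_s{sid}.log"
                log_file.write_text(log.to_text())
                logs[str(sid)] = str(log_file.relative_to(out))
            trials.append({
                "trial_id": trial_id,
                "trial_index": t_idx,
                "movement": mv.value,
                "position": entry.position,
                "end_range_deg": entry.end_range_deg,
                "marker_file": str(marker_file.relative_to(out)),
                "mocap_start": mocap_start.isoformat(),
                "mocap_rate_hz": config.mocap_rate_hz,
                "sensor_start": sensor_start.isoformat(),
                "sensor_rate_hz": config.sensor_rate_hz,
                "sensor_logs": logs,
            })
        manifest["participants"].append({"id": pid, "trials": trials})
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
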