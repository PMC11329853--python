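"""Per-trial synchronization, resampling and normalization of paired series.

Strain and kinematic streams are recorded by different devices with
different clocks-of-record and sampling rates; the only shared reference is
the computer timestamp of each stream's start.  Alignment expresses both
series on a common absolute clock, crops them to the overlapping interval,
and interpolates the strain onto the kinematic time base (which has the
higher bandwidth).  Each trial is then normalized independently: strain is
shifted so the movement starts at zero and scaled so that +1 is peak
tension and -1 peak compression; the reference angle is scaled to [-1, 1]
and, for movements whose convention-negative primary direction would
otherwise read negative (forward flexion, left lateral bend, right
rotation), multiplied by -1 so the primary movement direction is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

from .errors import AlignmentError, DataError, ParameterError
from .protocol import DEFAULT_FLIP_SET, Movement

__all__ = [
    "AlignedPair",
    "align_and_trim",
    "resample_to_common_base",
    "normalize_pair",
]


@dataclass
class AlignedPair:
    """A strain/angle pair on a shared uniform time base.

    After :func:`normalize_pair`, ``eps`` starts at zero with max|eps| = 1
    and ``angle`` has max|angle| = 1 with the primary movement direction
    positive (unless the series is degenerate).
    """

    t: np.ndarray
    eps: np.ndarray
    angle: np.ndarray
    movement: Movement
    sensor_id: int
    reference_angle_name: str
    participant_id: str | None = None
    trial_id: str | None = None
    normalized: bool = False
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if not (self.t.size == self.eps.size == self.angle.size):
            raise DataError("t, eps and angle must share one length")
        self.movement = Movement(self.movement)


def _crop(t: np.ndarray, y: np.ndarray, start_abs: float,
          lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    t_abs = start_abs + t
    keep = (t_abs >= lo - 1e-12) & (t_abs <= hi + 1e-12)
    return t_abs[keep] - lo, y[keep]


def align_and_trim(t_strain: np.ndarray, eps: np.ndarray, strain_start: datetime,
                   t_angle: np.ndarray, angle: np.ndarray, mocap_start: datetime,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Express both series on a common clock and crop to their overlap.

    ``t_strain``/``t_angle`` are relative to their stream's start
    timestamp.  Returns ``(t_strain', eps', t_angle', angle')`` with times
    measured from the start of the overlapping interval.

    Raises :class:`AlignmentError`, reporting both spans, when the streams
    do not overlap in absolute time.
    """
    t_strain = np.asarray(t_strain, dtype=float)
    t_angle = np.asarray(t_angle, dtype=float)
    offset = (strain_start - mocap_start).total_seconds()
    # absolute clock with the mocap start as epoch
    s_lo, s_hi = offset + t_strain[0], offset + t_strain[-1]
    a_lo, a_hi = t_angle[0], t_angle[-1]
    lo, hi = max(s_lo, a_lo), min(s_hi, a_hi)
    if hi <= lo:
        raise AlignmentError(
            f"streams do not overlap: strain spans [{s_lo:.3f}, {s_hi:.3f}] s, "
            f"kinematics spans [{a_lo:.3f}, {a_hi:.3f}] s (mocap clock)")
    ts, es = _crop(t_strain, np.asarray(eps, float), offset, lo, hi)
    ta, an = _crop(t_angle, np.asarray(angle, float), 0.0, lo, hi)
    if ts.size == 0 or ta.size == 0:
        raise AlignmentError("overlap contains no samples from one stream")
    return ts, es, ta, an


def resample_to_common_base(t_strain: np.ndarray, eps: np.ndarray,
                            t_angle: np.ndarray, angle: np.ndarray,
                            target_rate_hz: float | None = None,
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate the pair onto a shared time base.

    By default the strain is linearly interpolated onto the kinematic time
    base (no kinematic bandwidth is discarded); when ``target_rate_hz`` is
    given, both series are interpolated onto a uniform grid at that rate
    over the common span.  Returns ``(t, eps, angle)``.

    Requests reaching beyond either series by more than one sample period
    are refused (no extrapolation); within one period the edge value is
    held.
    """
    t_strain = np.asarray(t_strain, dtype=float)
    t_angle = np.asarray(t_angle, dtype=float)
    eps = np.asarray(eps, dtype=float)
    angle = np.asarray(angle, dtype=float)
    if target_rate_hz is not None:
        if target_rate_hz <= 0:
            raise ParameterError("target_rate_hz must be > 0")
        lo = max(t_strain[0], t_angle[0])
        hi = min(t_strain[-1], t_angle[-1])
        n = int(np.floor((hi - lo) * target_rate_hz)) + 1
        t_new = lo + np.arange(n) / target_rate_hz
        angle_i = np.interp(t_new, t_angle, angle)
    else:
        t_new = t_angle
        angle_i = angle
    dt = np.median(np.diff(t_strain)) if t_strain.size > 1 else 0.0
    if t_new[0] < t_strain[0] - dt - 1e-12 or t_new[-1] > t_strain[-1] + dt + 1e-12:
        raise AlignmentError(
            "resampling would extrapolate beyond the strain series by more "
            "than one sample period")
    eps_i = np.interp(t_new, t_strain, eps)
    return t_new, eps_i, angle_i


def normalize_pair(pair: AlignedPair,
                   flip_set: frozenset[Movement] = DEFAULT_FLIP_SET,
                   baseline_window_s: float = 0.25,
                   degenerate_tol: float = 1e-12) -> AlignedPair:
    """Apply the per-trial normalization and sign conventions.

    Strain: subtract the initial value (mean of the first
    ``baseline_window_s`` seconds) so the movement starts at zero strain,
    then divide by the maximum absolute value, so +1 is peak tension and
    -1 peak compression.  Angle: divide by the maximum absolute value,
    then multiply by -1 for movements in ``flip_set`` so the primary
    movement direction is positive.

    Identically-zero series are not scaled; the pair is flagged degenerate
    and excluded from correlation downstream.  Normalization is
    idempotent: an already-normalized pair is returned unchanged.
    """
    if pair.normalized:
        return pair
    t, eps, angle = pair.t, pair.eps.copy(), pair.angle.copy()
    mask = t <= t[0] + baseline_window_s
    eps = eps - eps[mask].mean()
    degenerate = False
    eps_peak = np.max(np.abs(eps)) if eps.size else 0.0
    if eps_peak > degenerate_tol:
        eps = eps / eps_peak
    else:
        degenerate = True
    ang_peak = np.max(np.abs(angle)) if angle.size else 0.0
    if ang_peak > degenerate_tol:
        angle = angle / ang_peak
    else:
        degenerate = True
    if pair.movement in flip_set:
        angle = -angle
    meta = dict(pair.meta)
    meta["flipped"] = pair.movement in flip_set
    meta["baseline_window_s"] = baseline_window_s
    return replace(pair, eps=eps, angle=angle, normalized=True,
                   degenerate=degenerate, meta=meta)
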