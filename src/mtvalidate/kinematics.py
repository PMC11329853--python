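"""Multisegmental lumbar spine kinematics from labeled marker trajectories.

The spine model has three rigid segments tracked by retroreflective markers:

* **upper lumbar** — markers lateral to the L1 spinous process (left/right)
  plus the L3 spinous-process marker;
* **lower lumbar** — markers lateral to L4 plus the L5 spinous marker;
* **pelvis** — bilateral PSIS, ASIS, posterior-pelvis and iliac-crest markers.

Each segment's anatomical frame is built from a mediolateral marker pair and
a midline reference: the ML axis points from the left to the right marker,
the SI axis is the component of the origin-to-reference vector orthogonal to
ML, and the PA axis completes the right-handed triad (ML x SI).  Relative
orientations (upper w.r.t. lower lumbar; lower lumbar w.r.t. pelvis) are
decomposed as Euler angles in the XYZ sequence, where the X component is
flexion/extension (about ML), Y is axial rotation (about SI) and Z is
lateral bend (about PA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import DataError, FormatError, GeometryError
from .protocol import MOVEMENT_PRIMARY_COMPONENT, Movement

__all__ = [
    "MarkerFrameSequence",
    "SegmentDefinition",
    "SpineModelDefinition",
    "SegmentFrame",
    "KinematicAngleSeries",
    "read_marker_tsv",
    "write_marker_tsv",
    "interpolate_gaps",
    "build_segment_frame",
    "euler_xyz",
    "euler_to_matrix",
    "compute_lumbar_angles",
    "primary_angle",
]

#: Threshold (degrees) on |theta_y| beyond which the XYZ decomposition is
#: close to its gimbal singularity and the sample is flagged.
GIMBAL_LIMIT_DEG = 89.0

_COMPONENT_NAMES = ("x", "y", "z")


# ---------------------------------------------------------------------------
# Marker containers and I/O
# ---------------------------------------------------------------------------

@dataclass
class MarkerFrameSequence:
    """Labeled 3D marker positions over time.

    Attributes
    ----------
    t : (n,) float array
        Frame times, seconds, strictly increasing.
    labels : tuple of str
        Marker labels, in column order.
    data : (n, m, 3) float array
        Positions in millimeters; NaN marks missing samples.
    """

    t: np.ndarray
    labels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.shape != (self.t.size, len(self.labels), 3):
            raise FormatError(
                f"data shape {self.data.shape} inconsistent with "
                f"{self.t.size} frames x {len(self.labels)} markers"
            )
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise FormatError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.t.size

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise FormatError(f"marker {label!r} not present") from None

    def positions(self, label: str) -> np.ndarray:
        """(n, 3) trajectory of one marker."""
        return self.data[:, self.index(label), :]

    def missing_mask(self, label: str) -> np.ndarray:
        """(n,) boolean mask of frames where the marker is missing."""
        return np.isnan(self.data[:, self.index(label), :]).any(axis=1)

    def copy(self) -> "MarkerFrameSequence":
        return MarkerFrameSequence(self.t.copy(), self.labels, self.data.copy())


def write_marker_tsv(seq: MarkerFrameSequence, path) -> None:
    """Write a Qualisys-export-style TSV: Frame, Time, then X/Y/Z per marker.

    Missing samples are written as empty fields.
    """
    cols = ["Frame", "Time"]
    for lab in seq.labels:
        cols += [f"{lab}_X", f"{lab}_Y", f"{lab}_Z"]
    n = seq.n_frames
    flat = seq.data.reshape(n, -1)
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(n):
            row = [str(i + 1), f"{seq.t[i]:.6f}"]
            row += ["" if np.isnan(v) else f"{v:.6f}" for v in flat[i]]
            fh.write("\t".join(row) + "\n")


def read_marker_tsv(path, required_labels=None) -> MarkerFrameSequence:
    """Read a marker trajectory TSV into a :class:`MarkerFrameSequence`.

    The dialect is a single header row of column labels (``Frame``, ``Time``,
    then ``<marker>_X/_Y/_Z`` triplets in millimeters) followed by one row
    per frame.  Blank or all-zero coordinate triplets mark gaps and are
    loaded as NaN.

    Raises
    ------
    FormatError
        If the file is empty, a required marker is absent, or the column
        layout is not X/Y/Z triplets.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty marker file") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: marker file has no frames")
    if "Time" not in df.columns:
        raise FormatError(f"{path}: missing Time column")
    coord_cols = [c for c in df.columns if c not in ("Frame", "Time")]
    labels: list[str] = []
    for c in coord_cols:
        if c.endswith("_X"):
            labels.append(c[:-2])
    for lab in labels:
        for suffix in ("_X", "_Y", "_Z"):
            if f"{lab}{suffix}" not in df.columns:
                raise FormatError(f"{path}: marker {lab} lacks column {lab}{suffix}")
    if required_labels is not None:
        absent = sorted(set(required_labels) - set(labels))
        if absent:
            raise FormatError(f"{path}: missing required markers {absent}")
    t = df["Time"].to_numpy(dtype=float)
    n, m = len(df), len(labels)
    data = np.empty((n, m, 3))
    for j, lab in enumerate(labels):
        for k, suffix in enumerate(("_X", "_Y", "_Z")):
            data[:, j, k] = pd.to_numeric(df[f"{lab}{suffix}"], errors="coerce")
    # an exactly (0, 0, 0) triplet is the conventional gap encoding
    zero = np.all(data == 0.0, axis=2)
    data[zero] = np.nan
    # partial NaN in a triplet counts as a fully missing sample
    anynan = np.isnan(data).any(axis=2)
    data[anynan] = np.nan
    return MarkerFrameSequence(t, tuple(labels), data)


def interpolate_gaps(seq: MarkerFrameSequence, max_gap_frames: int = 10) -> MarkerFrameSequence:
    """Fill missing marker samples by per-coordinate cubic interpolation.

    Gaps longer than ``max_gap_frames`` consecutive frames, or gaps touching
    either end of the recording (which would require extrapolation), raise
    :class:`DataError` naming the marker and frame span.
    """
    out = seq.copy()
    for j, lab in enumerate(seq.labels):
        missing = np.isnan(out.data[:, j, :]).any(axis=1)
        if not missing.any():
            continue
        # enumerate runs of missing frames
        idx = np.flatnonzero(missing)
        runs: list[tuple[int, int]] = []
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                runs.append((start, prev))
                start = i
            prev = i
        runs.append((start, prev))
        for a, b in runs:
            if a == 0 or b == seq.n_frames - 1:
                raise DataError(
                    f"marker {lab}: gap at frames {a}-{b} touches the recording "
                    "boundary and cannot be interpolated"
                )
            if b - a + 1 > max_gap_frames:
                raise DataError(
                    f"marker {lab}: gap of {b - a + 1} frames ({a}-{b}) exceeds "
                    f"max_gap_frames={max_gap_frames}"
                )
        valid = ~missing
        for k in range(3):
            spline = CubicSpline(seq.t[valid], out.data[valid, j, k])
            out.data[missing, j, k] = spline(seq.t[missing])
    return out


# ---------------------------------------------------------------------------
# Segment frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentDefinition:
    """Recipe for building one segment's anatomical frame from markers.

    ``ml_left``/``ml_right`` give the mediolateral pair; ``origin_markers``
    (midpoint) gives the origin, defaulting to the ML pair; ``si_reference``
    markers (midpoint) anchor the SI direction, which points from the
    reference toward the origin when ``si_reference_is_inferior`` (lumbar
    segments) and from the origin toward the reference otherwise (pelvis,
    whose iliac-crest reference lies superior to the PSIS origin).
    """

    name: str
    ml_left: str
    ml_right: str
    si_reference: tuple[str, ...]
    origin_markers: tuple[str, ...] | None = None
    si_reference_is_inferior: bool = True

    @property
    def required_markers(self) -> tuple[str, ...]:
        req = [self.ml_left, self.ml_right, *self.si_reference]
        if self.origin_markers:
            req += list(self.origin_markers)
        # preserve order, drop duplicates
        return tuple(dict.fromkeys(req))


@dataclass(frozen=True)
class SpineModelDefinition:
    """The three-segment lumbar spine model (upper, lower, pelvis)."""

    upper: SegmentDefinition = SegmentDefinition(
        "upper_lumbar", "L1_left", "L1_right", ("L3_spinous",))
    lower: SegmentDefinition = SegmentDefinition(
        "lower_lumbar", "L4_left", "L4_right", ("L5_spinous",))
    pelvis: SegmentDefinition = SegmentDefinition(
        "pelvis", "ASIS_left", "ASIS_right", ("crest_left", "crest_right"),
        origin_markers=("PSIS_left", "PSIS_right"),
        si_reference_is_inferior=False)

    @property
    def required_markers(self) -> tuple[str, ...]:
        req: list[str] = []
        for seg in (self.upper, self.lower, self.pelvis):
            req += list(seg.required_markers)
        return tuple(dict.fromkeys(req))


@dataclass(frozen=True)
class SegmentFrame:
    """Pose of one segment: origin (mm) and lab-frame rotation matrix.

    Columns of ``rotation`` are the segment's ML, SI and PA axes expressed
    in lab coordinates.
    """

    origin: np.ndarray
    rotation: np.ndarray


def _midpoint(seq_data: np.ndarray) -> np.ndarray:
    return seq_data.mean(axis=-2)


def _frames_from_points(left: np.ndarray, right: np.ndarray,
                        origin: np.ndarray, si_vec: np.ndarray,
                        expected_ml: np.ndarray | None = None) -> np.ndarray:
    """Vectorized orthonormal frame construction.

    Parameters are (..., 3) arrays.  Returns (..., 3, 3) rotation matrices
    with columns (ML, SI, PA).  Raises :class:`GeometryError` on collinear
    input or when the ML axis opposes ``expected_ml`` (a left/right marker
    swap produces a frame flipped 180 degrees about SI; the resulting
    orientation fails the handedness check against the expected lab
    direction).
    """
    ml = right - left
    nml = np.linalg.norm(ml, axis=-1, keepdims=True)
    if np.any(nml < 1e-9) or not np.all(np.isfinite(ml)):
        raise GeometryError("coincident or missing mediolateral markers")
    ml = ml / nml
    si = si_vec - (np.sum(si_vec * ml, axis=-1, keepdims=True)) * ml
    nsi = np.linalg.norm(si, axis=-1, keepdims=True)
    if np.any(nsi < 1e-9) or not np.all(np.isfinite(si)):
        raise GeometryError("markers are collinear; segment frame undefined")
    si = si / nsi
    pa = np.cross(ml, si)
    if expected_ml is not None:
        if np.any(np.sum(ml * expected_ml, axis=-1) <= 0):
            raise GeometryError(
                "ML axis opposes its expected lab direction "
                "(left/right markers swapped?)")
    R = np.stack([ml, si, pa], axis=-1)
    return R


def build_segment_frame(marker_positions: dict[str, np.ndarray],
                        segment: SegmentDefinition,
                        expected_ml: np.ndarray | None = np.array([1.0, 0.0, 0.0]),
                        ) -> SegmentFrame:
    """Build a single segment frame from one frame's marker positions.

    Parameters
    ----------
    marker_positions
        Mapping of marker label to (3,) position in mm.
    segment
        The frame recipe.
    expected_ml
        Expected approximate lab direction of the ML axis, used to detect
        left/right marker swaps; pass None to disable the check.
    """
    try:
        left = np.asarray(marker_positions[segment.ml_left], float)
        right = np.asarray(marker_positions[segment.ml_right], float)
        ref = _midpoint(np.stack(
            [np.asarray(marker_positions[m], float) for m in segment.si_reference]))
        if segment.origin_markers:
            origin = _midpoint(np.stack(
                [np.asarray(marker_positions[m], float) for m in segment.origin_markers]))
        else:
            origin = 0.5 * (left + right)
    except KeyError as e:
        raise GeometryError(f"segment {segment.name}: missing marker {e}") from None
    si_vec = (origin - ref) if segment.si_reference_is_inferior else (ref - origin)
    R = _frames_from_points(left, right, origin, si_vec, expected_ml)
    return SegmentFrame(origin=origin, rotation=R)


def _segment_frames_series(seq: MarkerFrameSequence, segment: SegmentDefinition,
                           check_ml: bool = True) -> np.ndarray:
    """(n, 3, 3) rotation matrices of one segment over all frames."""
    left = seq.positions(segment.ml_left)
    right = seq.positions(segment.ml_right)
    ref = _midpoint(np.stack([seq.positions(m) for m in segment.si_reference], axis=1))
    if segment.origin_markers:
        origin = _midpoint(np.stack(
            [seq.positions(m) for m in segment.origin_markers], axis=1))
    else:
        origin = 0.5 * (left + right)
    if np.isnan(left).any() or np.isnan(right).any() or np.isnan(ref).any():
        raise GeometryError(
            f"segment {segment.name}: missing marker samples; interpolate gaps first")
    si_vec = (origin - ref) if segment.si_reference_is_inferior else (ref - origin)
    expected = np.array([1.0, 0.0, 0.0]) if check_ml else None
    return _frames_from_points(left, right, origin, si_vec, expected)


# ---------------------------------------------------------------------------
# Euler angles
# ---------------------------------------------------------------------------

def euler_xyz(R: np.ndarray, degrees: bool = True):
    """Decompose rotation matrices as R = Rx(a) @ Ry(b) @ Rz(c).

    Parameters
    ----------
    R : (..., 3, 3) array
        Proper rotation matrices (orthonormal, det +1, checked to 1e-6).
    degrees
        Return angles in degrees (default) or radians.

    Returns
    -------
    angles : (..., 3) array
        (theta_x, theta_y, theta_z) on the canonical branch with theta_y in
        (-90, 90) degrees.
    gimbal : (...) boolean array
        True where |theta_y| exceeds the gimbal proximity limit (89 deg).
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise GeometryError(f"expected (..., 3, 3) rotation, got {R.shape}")
    RtR = np.einsum("...ji,...jk->...ik", R, R)
    eye = np.eye(3)
    if not np.allclose(RtR, eye, atol=1e-6) or not np.allclose(
            np.linalg.det(R), 1.0, atol=1e-6):
        raise GeometryError("input is not a proper rotation matrix")
    # R[0,2] = sin(b); R[1,2] = -sin(a) cos(b); R[2,2] = cos(a) cos(b)
    # R[0,1] = -cos(b) sin(c); R[0,0] = cos(b) cos(c)
    sb = np.clip(R[..., 0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    a = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    c = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    angles = np.stack([a, b, c], axis=-1)
    gimbal = np.abs(b) > np.deg2rad(GIMBAL_LIMIT_DEG)
    if degrees:
        angles = np.rad2deg(angles)
    return angles, gimbal


def euler_to_matrix(angles: np.ndarray, degrees: bool = True) -> np.ndarray:
    """Compose rotation matrices R = Rx(a) @ Ry(b) @ Rz(c) from XYZ angles."""
    angles = np.asarray(angles, dtype=float)
    if degrees:
        angles = np.deg2rad(angles)
    a, b, c = angles[..., 0], angles[..., 1], angles[..., 2]
    ca, sa = np.cos(a), np.sin(a)
    cb, sbn = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    R = np.empty(angles.shape[:-1] + (3, 3))
    R[..., 0, 0] = cb * cc
    R[..., 0, 1] = -cb * sc
    R[..., 0, 2] = sbn
    R[..., 1, 0] = ca * sc + sa * sbn * cc
    R[..., 1, 1] = ca * cc - sa * sbn * sc
    R[..., 1, 2] = -sa * cb
    R[..., 2, 0] = sa * sc - ca * sbn * cc
    R[..., 2, 1] = sa * cc + ca * sbn * sc
    R[..., 2, 2] = ca * cb
    return R


# ---------------------------------------------------------------------------
# Lumbar angles
# ---------------------------------------------------------------------------

@dataclass
class KinematicAngleSeries:
    """Upper- and lower-lumbar Euler angle triplets over time (degrees).

    ``upper_xyz`` is the upper lumbar segment relative to the lower lumbar
    segment; ``lower_xyz`` is the lower lumbar segment relative to the
    pelvis.  Component order is (x, y, z) = (flexion/extension, axial
    rotation, lateral bend).
    """

    t: np.ndarray
    upper_xyz: np.ndarray
    lower_xyz: np.ndarray
    gimbal_upper: np.ndarray = field(default=None)  # type: ignore[assignment]
    gimbal_lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = np.asarray(self.t).size
        for name in ("upper_xyz", "lower_xyz"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (n, 3):
                raise DataError(f"{name} must be (n, 3)")
            if not np.all(np.isfinite(arr)) or np.any(np.abs(arr) >= 180.0):
                raise DataError(f"{name} contains non-finite or out-of-range angles")
            setattr(self, name, arr)
        if self.gimbal_upper is None:
            self.gimbal_upper = np.zeros(n, dtype=bool)
        if self.gimbal_lower is None:
            self.gimbal_lower = np.zeros(n, dtype=bool)

    def angles(self, reference_angle_name: str) -> np.ndarray:
        if reference_angle_name == "upper_lumbar":
            return self.upper_xyz
        if reference_angle_name == "lower_lumbar":
            return self.lower_xyz
        raise DataError(f"unknown reference angle {reference_angle_name!r}")

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        for name, arr in (("upper", self.upper_xyz), ("lower", self.lower_xyz)):
            for k, comp in enumerate(_COMPONENT_NAMES):
                cols[f"{name}_{comp}_deg"] = arr[:, k]
        return pd.DataFrame(cols)


def _lowpass_markers(data: np.ndarray, t: np.ndarray,
                     cutoff_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass along the time axis.

    A no-op when the cutoff is at or above the (margin-adjusted) Nyquist
    frequency or the series is too short to pad.
    """
    from scipy.signal import butter, filtfilt

    n = data.shape[0]
    if n < 2:
        return data
    fs = 1.0 / np.median(np.diff(t))
    if cutoff_hz >= 0.475 * fs:
        return data
    b, a = butter(4, cutoff_hz, fs=fs)
    padlen = min(3 * max(len(a), len(b)), n - 2)
    if padlen < 1:
        return data
    return filtfilt(b, a, data, axis=0, padlen=padlen)


def compute_lumbar_angles(seq: MarkerFrameSequence,
                          model: SpineModelDefinition | None = None,
                          lowpass_cutoff_hz: float | None = 6.0,
                          ) -> KinematicAngleSeries:
    """Compute upper/lower lumbar Euler angle series from marker data.

    Marker trajectories are first low-pass filtered (zero-phase 4th-order
    Butterworth, default 6 Hz cutoff — far above voluntary trunk movement
    bandwidth but well below marker jitter; pass None to disable).  This
    matters because the L4-L5 inter-marker lever arm is short (~4 cm), so
    unfiltered sub-millimeter marker noise alone costs ~0.5 degree per
    frame in the lower segment orientation.

    Relative rotations are formed as R_ref^T @ R_segment (upper relative to
    lower lumbar, lower lumbar relative to pelvis) and decomposed in the
    XYZ sequence.
    """
    model = model or SpineModelDefinition()
    if lowpass_cutoff_hz is not None:
        seq = MarkerFrameSequence(
            seq.t, seq.labels, _lowpass_markers(seq.data, seq.t, lowpass_cutoff_hz))
    R_up = _segment_frames_series(seq, model.upper)
    R_low = _segment_frames_series(seq, model.lower)
    R_pel = _segment_frames_series(seq, model.pelvis)
    R_upper_rel = np.einsum("nji,njk->nik", R_low, R_up)
    R_lower_rel = np.einsum("nji,njk->nik", R_pel, R_low)
    upper, gim_u = euler_xyz(R_upper_rel)
    lower, gim_l = euler_xyz(R_lower_rel)
    return KinematicAngleSeries(t=seq.t, upper_xyz=upper, lower_xyz=lower,
                                gimbal_upper=gim_u, gimbal_lower=gim_l)


def primary_angle(kas: KinematicAngleSeries, movement: Movement,
                  reference_angle_name: str) -> tuple[np.ndarray, dict]:
    """Select the Euler component in the movement's primary plane.

    Returns the 1-D angle series (degrees) of the requested reference angle
    (``upper_lumbar`` or ``lower_lumbar``) and metadata recording which
    component was selected.
    """
    comp = MOVEMENT_PRIMARY_COMPONENT[Movement(movement)]
    series = kas.angles(reference_angle_name)[:, comp]
    meta = {
        "reference_angle": reference_angle_name,
        "component": _COMPONENT_NAMES[comp],
        "movement": Movement(movement).value,
    }
    return series, meta
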