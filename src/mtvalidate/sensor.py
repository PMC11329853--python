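"""Raw sensor-log decoding, strain derivation, filtering and quality control.

The tape's resistance is logged as hex-encoded integer counts (1 count =
0.1 Ohm) with ISO-8601 timestamps.  Decoding converts counts to ohms and
builds a linear time vector from the header start timestamp to the last
sample.  Strain is the fractional resistance change relative to a per-trial
baseline, eps = (R - R0) / R0 — the gauge factor K of the piezoresistive
relation dR/R = K eps may optionally be divided out, but the downstream
per-trial normalization removes the scale either way.

Outliers are removed with a Hampel filter (sliding window median / MAD
identifier), and whole streams whose resistance deviates grossly from the
cohort — more than ``threshold_sd`` (default 10) population SDs from the
mean resistance across participants for the same movement and sensor —
are flagged as failed and excluded from the validity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from .errors import DataError, FormatError, ParameterError, ParseError
from .protocol import Movement

__all__ = [
    "COUNT_OHMS",
    "ResistanceSeries",
    "StrainSeries",
    "QCEntry",
    "QCReport",
    "decode_log",
    "compute_strain",
    "hampel_filter",
    "flag_failed_streams",
]

#: Resistance resolution of the log dialect: 1 count = 0.1 Ohm.
COUNT_OHMS = 0.1

#: Gaussian consistency factor making the MAD an unbiased scale estimate.
MAD_SCALE = 1.4826


# ---------------------------------------------------------------------------
# Series containers
# ---------------------------------------------------------------------------

@dataclass
class ResistanceSeries:
    """Time-stamped resistance samples for one sensor in one trial."""

    t: np.ndarray
    r: np.ndarray
    sensor_id: int
    trial_id: str
    participant_id: str | None = None
    movement: Movement | None = None
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.t.size != self.r.size:
            raise DataError("t and r must have equal length")
        if self.t.size == 0:
            raise DataError("empty resistance series")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise FormatError("time vector must be strictly increasing")
        if not np.all(np.isfinite(self.r)) or np.any(self.r <= 0):
            raise DataError("resistance must be finite and positive")
        if self.movement is not None:
            self.movement = Movement(self.movement)


@dataclass
class StrainSeries:
    """Dimensionless strain proxy eps = (R - R0) / R0 for one stream."""

    t: np.ndarray
    eps: np.ndarray
    baseline_r0: float
    sensor_id: int
    trial_id: str
    participant_id: str | None = None
    movement: Movement | None = None
    start_time: datetime | None = None
    gauge_factor_used: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if not np.all(np.isfinite(self.eps)):
            raise DataError("strain must be finite")
        if not self.baseline_r0 > 0:
            raise DataError("baseline_r0 must be positive")
        if self.movement is not None:
            self.movement = Movement(self.movement)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _parse_header(lines: list[str], path) -> dict[str, str]:
    header = {}
    for i, line in enumerate(lines[:3]):
        if not line.startswith("#") or ":" not in line:
            raise FormatError(f"{path}: malformed header line {i + 1}: {line!r}")
        key, _, value = line.lstrip("# ").partition(":")
        header[key.strip()] = value.strip()
    for key in ("sensor_id", "trial_id", "start"):
        if key not in header:
            raise FormatError(f"{path}: header lacks {key!r}")
    return header


def decode_log(path, participant_id: str | None = None,
               movement: Movement | None = None) -> ResistanceSeries:
    """Decode a raw sensor log file into a :class:`ResistanceSeries`.

    Hex resistance fields are parsed to integer counts, scaled to ohms,
    and the time vector is generated linearly from the header start
    timestamp to the last sample timestamp (uniform spacing).

    Raises
    ------
    ParseError
        On a malformed hex field or timestamp, naming the line.
    FormatError
        On a malformed header or non-monotone timestamps.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 4:
        raise FormatError(f"{path}: log has no samples")
    header = _parse_header(lines, path)
    try:
        start = datetime.fromisoformat(header["start"])
    except ValueError:
        raise FormatError(f"{path}: bad start timestamp {header['start']!r}") from None
    counts = []
    stamps = []
    for line_no, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}: expected 'timestamp,hex', got {line!r}",
                             line_no=line_no)
        ts_str, hex_str = parts[0].strip(), parts[1].strip()
        try:
            stamps.append(datetime.fromisoformat(ts_str))
        except ValueError:
            raise ParseError(f"{path}: bad timestamp {ts_str!r}", line_no=line_no) from None
        try:
            counts.append(int(hex_str, 16))
        except ValueError:
            raise ParseError(f"{path}: bad hex field {hex_str!r}", line_no=line_no) from None
    if not counts:
        raise FormatError(f"{path}: log has no samples")
    for a, b in zip(stamps, stamps[1:]):
        if b <= a:
            raise FormatError(f"{path}: non-monotone timestamps around {b.isoformat()}")
    n = len(counts)
    span = (stamps[-1] - start).total_seconds()
    t = np.linspace(0.0, span, n) if n > 1 else np.zeros(1)
    r = np.asarray(counts, dtype=float) * COUNT_OHMS
    return ResistanceSeries(
        t=t, r=r, sensor_id=int(header["sensor_id"]),
        trial_id=header["trial_id"], participant_id=participant_id,
        movement=movement, start_time=start)


# ---------------------------------------------------------------------------
# Strain
# ---------------------------------------------------------------------------

def compute_strain(rs: ResistanceSeries, baseline_mode: str = "initial_window",
                   baseline_window_s: float = 0.5,
                   gauge_factor: float | None = None) -> StrainSeries:
    """Derive the strain proxy eps(t) = (R(t) - R0) / R0 for one stream.

    ``baseline_mode`` selects the per-trial baseline estimate: the mean of
    the first ``baseline_window_s`` seconds (default, robust to startup
    noise) or ``"first_sample"``.  When ``gauge_factor`` is given, strain
    is additionally divided by it (eps = dR / (K R0)).
    """
    if baseline_mode == "first_sample":
        r0 = float(rs.r[0])
    elif baseline_mode == "initial_window":
        mask = rs.t <= rs.t[0] + baseline_window_s
        r0 = float(rs.r[mask].mean())
    else:
        raise ParameterError(f"unknown baseline_mode {baseline_mode!r}")
    if r0 <= 0:
        raise DataError("estimated baseline resistance is non-positive")
    eps = (rs.r - r0) / r0
    if gauge_factor is not None:
        if gauge_factor <= 0:
            raise ParameterError("gauge_factor must be > 0")
        eps = eps / gauge_factor
    return StrainSeries(
        t=rs.t, eps=eps, baseline_r0=r0, sensor_id=rs.sensor_id,
        trial_id=rs.trial_id, participant_id=rs.participant_id,
        movement=rs.movement, start_time=rs.start_time,
        gauge_factor_used=gauge_factor)


# ---------------------------------------------------------------------------
# Hampel filter
# ---------------------------------------------------------------------------

def hampel_filter(x: np.ndarray, window_halfwidth: int = 5,
                  n_mad: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window median/MAD outlier filter.

    Sample i is replaced by the median of the window
    ``x[i-k : i+k+1]`` (truncated at the edges) whenever
    ``|x_i - median_i| > n_mad * 1.4826 * MAD_i``.  Returns the filtered
    series and a boolean mask of replaced samples.
    """
    if window_halfwidth < 1:
        raise ParameterError("window_halfwidth must be >= 1")
    if n_mad <= 0:
        raise ParameterError("n_mad must be > 0")
    x = np.asarray(x, dtype=float)
    n = x.size
    if 2 * window_halfwidth + 1 > n:
        raise ParameterError(
            f"window of {2 * window_halfwidth + 1} exceeds series length {n}")
    out = x.copy()
    mask = np.zeros(n, dtype=bool)
    k = window_halfwidth
    for i in range(n):
        lo = max(0, i - k)
        hi = min(n, i + k + 1)
        w = x[lo:hi]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if np.abs(x[i] - med) > n_mad * MAD_SCALE * mad:
            out[i] = med
            mask[i] = True
    return out, mask


def hampel_filter_series(rs: ResistanceSeries, window_halfwidth: int = 5,
                         n_mad: float = 3.0) -> tuple[ResistanceSeries, np.ndarray]:
    """Apply :func:`hampel_filter` to a resistance series."""
    filtered, mask = hampel_filter(rs.r, window_halfwidth, n_mad)
    cleaned = ResistanceSeries(
        t=rs.t, r=filtered, sensor_id=rs.sensor_id, trial_id=rs.trial_id,
        participant_id=rs.participant_id, movement=rs.movement,
        start_time=rs.start_time)
    return cleaned, mask


# ---------------------------------------------------------------------------
# Stream-level quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCEntry:
    """Quality-control result for one stream."""

    trial_id: str
    participant_id: str | None
    movement: Movement
    sensor_id: int
    statistic: float
    population_mean: float
    population_sd: float
    threshold_sd: float
    flagged: bool


@dataclass
class QCReport:
    """Cohort-level quality-control report."""

    entries: list[QCEntry]
    threshold_sd: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n_streams(self) -> int:
        return len(self.entries)

    @property
    def n_flagged(self) -> int:
        return sum(e.flagged for e in self.entries)

    @property
    def removal_fraction(self) -> float:
        return self.n_flagged / self.n_streams if self.entries else 0.0

    def flagged_keys(self) -> set[tuple]:
        return {(e.participant_id, e.movement, e.sensor_id, e.trial_id)
                for e in self.entries if e.flagged}

    def to_dict(self) -> dict:
        return {
            "threshold_sd": self.threshold_sd,
            "n_streams": self.n_streams,
            "n_flagged": self.n_flagged,
            "removal_fraction": self.removal_fraction,
            "warnings": list(self.warnings),
            "entries": [
                {"trial_id": e.trial_id, "participant_id": e.participant_id,
                 "movement": e.movement.value, "sensor_id": e.sensor_id,
                 "statistic": e.statistic, "population_mean": e.population_mean,
                 "population_sd": e.population_sd, "flagged": e.flagged}
                for e in self.entries
            ],
        }


def flag_failed_streams(streams: list[ResistanceSeries],
                        threshold_sd: float = 10.0) -> QCReport:
    """Flag streams whose mean resistance deviates grossly from the cohort.

    Streams are grouped by (movement, sensor) across participants; each
    stream's statistic is its trial-mean resistance, compared with the
    leave-one-out population mean and SD of the remaining streams in the
    group.  A stream is flagged when
    ``|statistic - mean_loo| > threshold_sd * sd_loo``.  Leave-one-out
    statistics keep a gross failure from masking itself by inflating the
    pooled SD, and conversely keep a failure from dragging healthy streams
    over the threshold.

    Groups with fewer than 3 streams cannot be flagged (a single-sample SD
    is meaningless); a warning is recorded instead.
    """
    if threshold_sd <= 0:
        raise ParameterError("threshold_sd must be > 0")
    groups: dict[tuple, list[ResistanceSeries]] = {}
    for s in streams:
        if s.movement is None:
            raise DataError(f"stream {s.trial_id}: movement metadata required for QC")
        groups.setdefault((s.movement, s.sensor_id), []).append(s)
    entries: list[QCEntry] = []
    warn_msgs: list[str] = []
    for (mv, sid), members in groups.items():
        stats = np.array([float(m.r.mean()) for m in members])
        if len(members) < 3:
            msg = (f"group ({mv.value}, sensor {sid}) has {len(members)} "
                   "stream(s); SD undefined, nothing flagged")
            warn_msgs.append(msg)
            warnings.warn(msg, stacklevel=2)
            for m, stat in zip(members, stats):
                entries.append(QCEntry(m.trial_id, m.participant_id, mv, sid,
                                       float(stat), float(stats.mean()), 0.0,
                                       threshold_sd, False))
            continue
        for j, (m, stat) in enumerate(zip(members, stats)):
            rest = np.delete(stats, j)
            mu = float(rest.mean())
            sd = float(rest.std(ddof=0))
            flagged = bool(abs(stat - mu) > threshold_sd * sd)
            entries.append(QCEntry(m.trial_id, m.participant_id, mv, sid,
                                   float(stat), mu, sd, threshold_sd, flagged))
    return QCReport(entries=entries, threshold_sd=threshold_sd,
                    warnings=warn_msgs)
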