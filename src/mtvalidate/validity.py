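"""Concurrent-validity analysis: zero-lag cross-correlation and aggregation.

Each tape is compared against the kinematic angle of the adjacent spinal
region: sensors 1-4 against the upper lumbar angle (L1-L3 relative to
L4-L5) and sensors 5-6 against the lower lumbar angle (L4-L5 relative to
pelvis).  The statistic is the cross-correlation coefficient at zero phase
shift,

    r0 = sum(x_i y_i) / sqrt(sum(x_i^2) sum(y_i^2)),

i.e. coefficient normalization without demeaning — on zero-shifted,
[-1, 1]-normalized inputs this matches the behaviour of MATLAB-style
``xcorr(..., 'coeff')`` at lag zero.  A demeaned (Pearson) variant is
available behind a flag.  Positive coefficients indicate the tape was in
tension with increasing reference angle, negative coefficients indicate
compression.  Coefficients are aggregated as median and range per
(movement, sensor) across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignedPair
from .errors import ConfigurationError, ParameterError
from .protocol import Movement

__all__ = [
    "DEFAULT_SENSOR_REFERENCE_MAP",
    "TrialResult",
    "zero_lag_xcorr",
    "xcorr_profile",
    "evaluate_trial",
    "aggregate",
    "plot_validity_heatmap",
]

#: Reference kinematic angle for each tape: the upper four sensors overlie
#: the upper lumbar junctions, the lower pair the lower lumbar junctions.
DEFAULT_SENSOR_REFERENCE_MAP: dict[int, str] = {
    1: "upper_lumbar", 2: "upper_lumbar", 3: "upper_lumbar",
    4: "upper_lumbar", 5: "lower_lumbar", 6: "lower_lumbar",
}

MOVEMENT_ORDER = [m.value for m in Movement]


def zero_lag_xcorr(x: np.ndarray, y: np.ndarray, demean: bool = False) -> float:
    """Cross-correlation coefficient at zero phase shift.

    Returns NaN when either series has zero energy (degenerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D series")
    if demean:
        x = x - x.mean()
        y = y - y.mean()
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    if denom == 0.0 or not np.isfinite(denom):
        return float("nan")
    return float(np.dot(x, y) / denom)


def xcorr_profile(x: np.ndarray, y: np.ndarray, demean: bool = False,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Full normalized cross-correlation sequence over all lags.

    Returns ``(lags, r)`` with the same coefficient normalization as
    :func:`zero_lag_xcorr`; ``r[lags == 0]`` equals the zero-lag
    coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D series")
    if demean:
        x = x - x.mean()
        y = y - y.mean()
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    n = x.size
    lags = np.arange(-(n - 1), n)
    r = np.correlate(x, y, mode="full")[::-1]
    if denom == 0.0:
        return lags, np.full(r.shape, np.nan)
    return lags, r / denom


@dataclass(frozen=True)
class TrialResult:
    """Zero-lag coefficient and its tension/compression interpretation."""

    participant_id: str | None
    movement: Movement
    sensor_id: int
    reference_angle_name: str
    r0: float
    interpretation: str | None
    degenerate: bool


def evaluate_trial(pair: AlignedPair,
                   reference_map: dict[int, str] | None = None,
                   demean: bool = False) -> TrialResult:
    """Correlate one normalized strain/angle pair at zero lag.

    The pair must reference the angle the sensor map assigns to its
    sensor.  Degenerate (zero-variance) pairs yield a missing coefficient.
    """
    ref_map = reference_map or DEFAULT_SENSOR_REFERENCE_MAP
    if pair.sensor_id not in ref_map:
        raise ConfigurationError(f"sensor {pair.sensor_id} missing from reference map")
    expected = ref_map[pair.sensor_id]
    if pair.reference_angle_name != expected:
        raise ConfigurationError(
            f"sensor {pair.sensor_id} must be compared with {expected}, "
            f"got {pair.reference_angle_name}")
    if pair.degenerate:
        return TrialResult(pair.participant_id, pair.movement, pair.sensor_id,
                           pair.reference_angle_name, float("nan"), None, True)
    r0 = zero_lag_xcorr(pair.eps, pair.angle, demean=demean)
    if np.isnan(r0):
        return TrialResult(pair.participant_id, pair.movement, pair.sensor_id,
                           pair.reference_angle_name, r0, None, True)
    interp = "tension" if r0 > 0 else "compression"
    return TrialResult(pair.participant_id, pair.movement, pair.sensor_id,
                       pair.reference_angle_name, r0, interp, False)


def results_to_frame(results: list[TrialResult]) -> pd.DataFrame:
    """Long-form per-trial table of coefficients."""
    return pd.DataFrame([
        {"participant": r.participant_id, "movement": r.movement.value,
         "sensor_id": r.sensor_id, "reference_angle": r.reference_angle_name,
         "r0": r.r0, "interpretation": r.interpretation,
         "degenerate": r.degenerate}
        for r in results
    ])


def aggregate(rows: pd.DataFrame) -> pd.DataFrame:
    """Summarize coefficients per (movement, sensor) across participants.

    Expects the long-form frame from :func:`results_to_frame` (columns
    ``movement``, ``sensor_id``, ``r0``; NaN r0 counts as missing).
    Returns one row per cell with median, min, max, n and n_missing;
    missing values are excluded from the order statistics, never imputed.
    An all-missing cell has NaN summaries.
    """
    for col in ("movement", "sensor_id", "r0"):
        if col not in rows.columns:
            raise ParameterError(f"rows lacks required column {col!r}")
    recs = []
    for (mv, sid), grp in rows.groupby(["movement", "sensor_id"], sort=True):
        vals = grp["r0"].dropna()
        recs.append({
            "movement": mv, "sensor_id": sid,
            "median_r0": vals.median() if len(vals) else np.nan,
            "min_r0": vals.min() if len(vals) else np.nan,
            "max_r0": vals.max() if len(vals) else np.nan,
            "n": int(len(vals)),
            "n_missing": int(grp["r0"].isna().sum()),
        })
    out = pd.DataFrame(recs)
    out["movement"] = pd.Categorical(out["movement"], categories=MOVEMENT_ORDER,
                                     ordered=True)
    return out.sort_values(["movement", "sensor_id"]).reset_index(drop=True)


def validity_matrix(rows: pd.DataFrame, participant: str | None = None,
                    ) -> pd.DataFrame:
    """Pivot per-trial coefficients into a movement x sensor matrix."""
    df = rows if participant is None else rows[rows["participant"] == participant]
    mat = df.pivot_table(index="movement", columns="sensor_id", values="r0",
                         aggfunc="median")
    return mat.reindex(MOVEMENT_ORDER)


def plot_validity_heatmap(rows: pd.DataFrame, path=None):
    """Render the per-participant coefficient matrix as a color-scaled grid.

    Green encodes positive correlation (tape tension), yellow negative
    (compression), white near zero, gray missing — darker shades for
    stronger correlation.  Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "tension_compression", [(0.0, "#b8a400"), (0.5, "#ffffff"), (1.0, "#1a7a1a")])
    cmap.set_bad("#bbbbbb")
    participants = sorted(p for p in rows["participant"].dropna().unique())
    if not participants:
        participants = [None]
    ncols = len(participants)
    fig, axes = plt.subplots(1, ncols, figsize=(3.2 * ncols, 3.6), squeeze=False)
    for ax, pid in zip(axes[0], participants):
        mat = validity_matrix(rows, participant=pid)
        ax.imshow(np.ma.masked_invalid(mat.to_numpy(dtype=float)),
                  cmap=cmap, vmin=-1.0, vmax=1.0, aspect="auto")
        ax.set_xticks(range(mat.shape[1]),
                      [f"S{c}" for c in mat.columns], fontsize=7)
        ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
        ax.set_title(str(pid), fontsize=8)
    fig.suptitle("Zero-lag cross-correlation: strain vs reference angle",
                 fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
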