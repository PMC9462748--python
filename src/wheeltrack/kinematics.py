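"""Distance and velocity analysis of sampled rotation counts.

Converts a cumulative-count log column into a distance series (counts x
circumference), a raw per-interval velocity, and a trailing moving-average
velocity (default window 4 samples — at 4 Hz a one-second smoother, the
convention used when plotting wheel speed). Phase summaries break totals
down by contiguous light/dark intervals; bout detection segments running
from rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import SerialLog
from .simulator import LightDarkSchedule, WheelGeometry

__all__ = [
    "ActivitySeries",
    "PhaseSummary",
    "BoutTable",
    "counts_to_activity",
    "summarize_phases",
    "detect_bouts",
]


@dataclass
class ActivitySeries:
    """Per-sample distance/velocity series for one cage.

    velocity_raw[k] = (distance[k] - distance[k-1]) / sample_period with
    velocity_raw[0] = 0; velocity_smooth is a trailing moving average
    (partial windows average the samples available so far).
    """

    times: np.ndarray  # s offsets from wall_start
    distance: np.ndarray  # cumulative cm
    velocity_raw: np.ndarray  # cm/s
    velocity_smooth: np.ndarray  # cm/s
    phase: np.ndarray  # 'light' | 'dark' per sample
    sample_period: float
    sensor_id: str = "s1"

    @property
    def total_distance(self) -> float:
        return float(self.distance[-1]) if self.distance.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "distance_cm": self.distance,
                "velocity_raw_cm_s": self.velocity_raw,
                "velocity_smooth_cm_s": self.velocity_smooth,
                "phase": self.phase,
            }
        )


@dataclass
class PhaseSummary:
    """One row per contiguous light or dark interval."""

    rows: pd.DataFrame  # phase, start_s, end_s, distance_cm, mean_velocity_cm_s,
    #                     peak_smooth_velocity_cm_s, active_fraction

    @property
    def total_distance(self) -> float:
        return float(self.rows["distance_cm"].sum())


@dataclass
class BoutTable:
    bouts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["start_s", "end_s", "distance_cm", "mean_speed_cm_s"]
        )
    )
    rest_gaps: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_bouts(self) -> int:
        return len(self.bouts)


def counts_to_activity(
    log: SerialLog,
    geometry: WheelGeometry,
    schedule: LightDarkSchedule,
    smooth_window: int = 4,
    sensor_id: str | None = None,
) -> ActivitySeries:
    """Derive an ActivitySeries from one sensor column of a SerialLog.

    The log must be monotone (run :func:`wheeltrack.log_io.detect_counter_resets`
    first if an acquisition restart left a decreasing column).
    """
    if sensor_id is None:
        sensor_id = log.sensor_ids[0]
    j = log.sensor_ids.index(sensor_id)
    counts = log.samples[:, j]
    if counts.size > 1 and np.any(np.diff(counts) < 0):
        raise ValueError(
            f"sensor {sensor_id!r} counts are non-monotone; "
            "run detect_counter_resets before analysis"
        )
    times = log.times
    distance = counts.astype(float) * geometry.circumference
    velocity_raw = np.zeros_like(distance)
    if distance.size > 1:
        velocity_raw[1:] = np.diff(distance) / log.sample_period
    velocity_smooth = (
        pd.Series(velocity_raw).rolling(smooth_window, min_periods=1).mean().to_numpy()
    )
    phase = schedule.phase_array(times, log.wall_start)
    return ActivitySeries(
        times=times,
        distance=distance,
        velocity_raw=velocity_raw,
        velocity_smooth=velocity_smooth,
        phase=phase,
        sample_period=log.sample_period,
        sensor_id=sensor_id,
    )


def summarize_phases(
    series: ActivitySeries, schedule: LightDarkSchedule | None = None
) -> PhaseSummary:
    """Summarise activity per contiguous light/dark interval.

    Each sample's distance increment is attributed to that sample's phase
    interval, so per-interval distances sum to the series total exactly.
    """
    _ = schedule  # phase labels already on the series
    if series.times.size == 0:
        return PhaseSummary(
            rows=pd.DataFrame(
                columns=[
                    "phase",
                    "start_s",
                    "end_s",
                    "distance_cm",
                    "mean_velocity_cm_s",
                    "peak_smooth_velocity_cm_s",
                    "active_fraction",
                ]
            )
        )
    phase = series.phase
    boundaries = [0] + [
        k for k in range(1, phase.size) if phase[k] != phase[k - 1]
    ] + [phase.size]
    increments = np.zeros_like(series.distance)
    if series.distance.size > 1:
        increments[1:] = np.diff(series.distance)
    rows = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        sl = slice(a, b)
        vel = series.velocity_raw[sl]
        rows.append(
            {
                "phase": phase[a],
                "start_s": series.times[a],
                "end_s": series.times[b - 1],
                "distance_cm": float(increments[sl].sum()),
                "mean_velocity_cm_s": float(vel.mean()),
                "peak_smooth_velocity_cm_s": float(series.velocity_smooth[sl].max()),
                "active_fraction": float((vel > 0).mean()),
            }
        )
    return PhaseSummary(rows=pd.DataFrame(rows))


def detect_bouts(
    series: ActivitySeries, min_speed: float = 1.0, min_gap: float = 60.0
) -> BoutTable:
    """Segment running bouts from rest.

    A bout is a maximal run of samples with ``velocity_raw >= min_speed``;
    bouts separated by a rest shorter than ``min_gap`` seconds are merged.
    ``rest_gaps`` holds the complementary rest durations (including any
    leading/trailing rest).
    """
    if series.times.size == 0:
        return BoutTable()
    active = series.velocity_raw >= min_speed
    period = series.sample_period
    # raw active runs as sample-index [start, end) pairs
    runs: list[list[int]] = []
    start = None
    for k, a in enumerate(active):
        if a and start is None:
            start = k
        elif not a and start is not None:
            runs.append([start, k])
            start = None
    if start is not None:
        runs.append([start, active.size])
    # merge runs separated by gaps shorter than min_gap
    merged: list[list[int]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1]) * period < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    increments = np.zeros_like(series.distance)
    if series.distance.size > 1:
        increments[1:] = np.diff(series.distance)
    bout_rows = []
    for a, b in merged:
        # sample k covers the interval ((k-1)*p, k*p]
        start_s = max(0.0, (a - 1) * period)
        end_s = (b - 1) * period
        dist = float(increments[a:b].sum())
        dur = max(end_s - start_s, period)
        bout_rows.append(
            {
                "start_s": start_s,
                "end_s": end_s,
                "distance_cm": dist,
                "mean_speed_cm_s": dist / dur,
            }
        )
    gaps = []
    prev_end = 0.0
    for row in bout_rows:
        if row["start_s"] > prev_end:
            gaps.append(row["start_s"] - prev_end)
        prev_end = row["end_s"]
    total_time = series.times[-1] if series.times.size else 0.0
    if total_time > prev_end:
        gaps.append(total_time - prev_end)
    bouts = (
        pd.DataFrame(bout_rows)
        if bout_rows
        else pd.DataFrame(columns=["start_s", "end_s", "distance_cm", "mean_speed_cm_s"])
    )
    return BoutTable(bouts=bouts, rest_gaps=np.array(gaps))


def plot_activity(series: ActivitySeries, ax=None):
    """Distance + smoothed velocity with shaded dark phases (matplotlib axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    ax.plot(series.times / 3600, series.distance / 1e5, color="tab:blue",
            label="distance (km)")
    ax2 = ax.twinx()
    ax2.plot(series.times / 3600, series.velocity_smooth, color="tab:red",
             alpha=0.6, label="velocity (cm/s)")
    dark = series.phase == "dark"
    if dark.any():
        t_h = series.times / 3600
        in_dark = False
        start = 0.0
        for k, d in enumerate(dark):
            if d and not in_dark:
                start, in_dark = t_h[k], True
            elif not d and in_dark:
                ax.axvspan(start, t_h[k], color="navy", alpha=0.08)
                in_dark = False
        if in_dark:
            ax.axvspan(start, t_h[-1], color="navy", alpha=0.08)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("distance (km)", color="tab:blue")
    ax2.set_ylabel("velocity (cm/s)", color="tab:red")
    return ax
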