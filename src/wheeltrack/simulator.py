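"""Ground-truth wheel rotation simulators.

Two modes are provided. The *robotic* mode reproduces a mechanical
validation run: a foam wheel driven at piecewise-constant rotation rates,
so rotation-completion times are exactly equally spaced within each
segment. The *virtual mouse* mode generates nocturnal, bout-structured
running: bout onsets follow an inhomogeneous Poisson process whose rate
switches between a dark-phase and a light-phase value, bout durations are
gamma distributed, and the running speed within a bout is Gaussian
(clipped at zero). Laboratory mice concentrate voluntary running in the
dark phase and cover roughly 3-16 km per night; the default preset is
calibrated to sit mid-band (~6-8 km per 12 h dark phase).

Rotation times are continuous float offsets in seconds from trace start;
discretisation onto a sampling grid happens only in the acquisition
emulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, time
from typing import Sequence

import numpy as np

__all__ = [
    "WheelGeometry",
    "RotationTrace",
    "SpeedProfile",
    "LightDarkSchedule",
    "MouseActivityParams",
    "NOCTURNAL_PRESET",
    "simulate_robotic_run",
    "simulate_mouse_activity",
    "trace_total_distance",
]

#: tolerance for "rotation k lands exactly on the segment end" float fuzz
_EPS = 1e-9


@dataclass(frozen=True)
class WheelGeometry:
    """Running-wheel geometry.

    Parameters
    ----------
    magnet_path_diameter : float
        Diameter of the circle traced by the magnet, in cm. Home-cage
        running discs are typically 15-20 cm across. There is no default:
        the experiment configuration must state it.
    circumference : float, optional
        Distance covered per rotation, in cm. Defaults to
        ``pi * magnet_path_diameter``; may be overridden (e.g. when the
        wheel was calibrated directly).
    """

    magnet_path_diameter: float
    circumference: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.magnet_path_diameter > 0:
            raise ValueError(
                f"magnet_path_diameter must be > 0, got {self.magnet_path_diameter}"
            )
        if self.circumference is None:
            object.__setattr__(
                self, "circumference", math.pi * self.magnet_path_diameter
            )
        if not self.circumference > 0:
            raise ValueError(f"circumference must be > 0, got {self.circumference}")


@dataclass(frozen=True)
class RotationTrace:
    """Ground-truth rotation-completion times for one wheel.

    ``rotation_times`` is a strictly increasing float array of offsets in
    seconds from ``wall_start``; an empty array is a valid trace (no
    running). ``duration`` bounds every rotation time.
    """

    rotation_times: np.ndarray
    duration: float
    wall_start: datetime = datetime(2026, 1, 1, 6, 0, 0)

    def __post_init__(self) -> None:
        times = np.asarray(self.rotation_times, dtype=float)
        object.__setattr__(self, "rotation_times", times)
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("rotation_times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration + _EPS:
                raise ValueError("rotation_times must lie in [0, duration]")

    @property
    def n_rotations(self) -> int:
        return int(self.rotation_times.size)


@dataclass(frozen=True)
class SpeedProfile:
    """Piecewise-constant rotation-rate profile: (duration_s, rev_per_s) segments."""

    segments: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        segs = [(float(d), float(r)) for d, r in self.segments]
        object.__setattr__(self, "segments", tuple(segs))
        for d, r in segs:
            if d <= 0:
                raise ValueError(f"segment duration must be > 0, got {d}")
            if r < 0:
                raise ValueError(f"rotation rate must be >= 0, got {r}")

    @property
    def duration(self) -> float:
        return float(sum(d for d, _ in self.segments))


@dataclass(frozen=True)
class LightDarkSchedule:
    """24 h-periodic light/dark schedule given by dark onset/offset clock times.

    The dark interval runs from ``dark_onset`` to ``dark_offset`` and may
    wrap midnight (the usual vivarium 18:00-06:00 dark phase does).
    """

    dark_onset: time = time(18, 0)
    dark_offset: time = time(6, 0)

    def __post_init__(self) -> None:
        if self.dark_onset == self.dark_offset:
            raise ValueError("dark_onset and dark_offset must differ")

    @staticmethod
    def _hours(t: time) -> float:
        return t.hour + t.minute / 60 + t.second / 3600

    def is_dark(self, wall_time: datetime) -> bool:
        h = wall_time.hour + wall_time.minute / 60 + wall_time.second / 3600
        h += wall_time.microsecond / 3.6e9
        on, off = self._hours(self.dark_onset), self._hours(self.dark_offset)
        if on < off:
            return on <= h < off
        return h >= on or h < off

    def is_dark_offset(self, offset_s: float, wall_start: datetime) -> bool:
        """Phase at ``wall_start + offset_s`` (vectorisable via phase_array)."""
        h0 = (
            wall_start.hour
            + wall_start.minute / 60
            + wall_start.second / 3600
            + wall_start.microsecond / 3.6e9
        )
        h = (h0 + offset_s / 3600.0) % 24.0
        on, off = self._hours(self.dark_onset), self._hours(self.dark_offset)
        if on < off:
            return bool(on <= h < off)
        return bool(h >= on or h < off)

    def phase_array(self, offsets_s: np.ndarray, wall_start: datetime) -> np.ndarray:
        """Vector of ``'dark'``/``'light'`` labels for offsets from wall_start."""
        h0 = (
            wall_start.hour
            + wall_start.minute / 60
            + wall_start.second / 3600
            + wall_start.microsecond / 3.6e9
        )
        h = (h0 + np.asarray(offsets_s, dtype=float) / 3600.0) % 24.0
        on, off = self._hours(self.dark_onset), self._hours(self.dark_offset)
        if on < off:
            dark = (h >= on) & (h < off)
        else:
            dark = (h >= on) | (h < off)
        return np.where(dark, "dark", "light")

    def next_transition(self, offset_s: float, wall_start: datetime) -> float:
        """Offset (s) of the next light<->dark boundary strictly after offset_s."""
        h0 = (
            wall_start.hour
            + wall_start.minute / 60
            + wall_start.second / 3600
            + wall_start.microsecond / 3.6e9
        )
        h = (h0 + offset_s / 3600.0) % 24.0
        on, off = self._hours(self.dark_onset), self._hours(self.dark_offset)
        gaps = []
        for b in (on, off):
            g = (b - h) % 24.0
            if g <= 1e-12:
                g = 24.0
            gaps.append(g)
        return offset_s + min(gaps) * 3600.0


@dataclass(frozen=True)
class MouseActivityParams:
    """Parameters of the bout-structured virtual-mouse model.

    dark_bout_rate / light_bout_rate : bout onsets per hour in each phase.
    bout_duration_mean / bout_duration_shape : gamma bout-duration model
    (mean in seconds, dimensionless shape; scale = mean / shape).
    run_speed_mean / run_speed_sd : per-bout linear speed draw, cm/s,
    Gaussian clipped below at 0.
    """

    dark_bout_rate: float = 12.0
    light_bout_rate: float = 0.5
    bout_duration_mean: float = 400.0
    bout_duration_shape: float = 2.0
    run_speed_mean: float = 28.0
    run_speed_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dark_bout_rate < 0 or self.light_bout_rate < 0:
            raise ValueError("bout rates must be >= 0")
        if self.bout_duration_mean <= 0 or self.bout_duration_shape <= 0:
            raise ValueError("bout duration mean and shape must be > 0")
        if self.run_speed_mean <= 0 or self.run_speed_sd < 0:
            raise ValueError("run_speed_mean must be > 0 and run_speed_sd >= 0")

    def with_seed(self, seed: int) -> "MouseActivityParams":
        return replace(self, seed=seed)


#: Default nocturnal preset: ~62 bouts per 12 h dark phase averaging ~400 s at
#: ~28 cm/s, i.e. a mid-band ~7 km night on a 50 cm wheel.
NOCTURNAL_PRESET = MouseActivityParams()


def simulate_robotic_run(
    profile: SpeedProfile, geometry: WheelGeometry, wall_start: datetime | None = None
) -> RotationTrace:
    """Drive the wheel at piecewise-constant rotation rates.

    Within a segment of duration ``d`` and rate ``r`` (rev/s), rotations
    complete at offsets ``k / r`` for ``k = 1..floor(d * r)`` relative to
    the segment start; zero-rate segments contribute no rotations. The
    geometry does not affect rotation times (it converts counts to
    distance downstream) but is part of the run description.
    """
    if not profile.segments:
        raise ValueError("profile must contain at least one segment")
    _ = geometry  # geometry validated on construction; rotation times are rate-only
    times: list[np.ndarray] = []
    t0 = 0.0
    for d, r in profile.segments:
        if r > 0:
            n = int(math.floor(d * r + _EPS))
            if n:
                k = np.arange(1, n + 1, dtype=float)
                times.append(t0 + k / r)
        t0 += d
    rotation_times = np.concatenate(times) if times else np.empty(0)
    kwargs = {} if wall_start is None else {"wall_start": wall_start}
    return RotationTrace(rotation_times, duration=profile.duration, **kwargs)


def _draw_bout_onset(
    t: float,
    duration: float,
    params: MouseActivityParams,
    schedule: LightDarkSchedule,
    wall_start: datetime,
    rng: np.random.Generator,
) -> float | None:
    """Next bout onset after t for a piecewise-constant-rate Poisson process.

    Exponential gaps are memoryless, so the onset is simulated exactly by
    redrawing from the new rate whenever a phase boundary is crossed first.
    """
    while t < duration:
        dark = schedule.is_dark_offset(t, wall_start)
        rate_h = params.dark_bout_rate if dark else params.light_bout_rate
        boundary = min(schedule.next_transition(t, wall_start), duration)
        if rate_h <= 0:
            t = boundary
            continue
        gap = rng.exponential(3600.0 / rate_h)
        if t + gap < boundary:
            return t + gap
        t = boundary
    return None


def simulate_mouse_activity(
    params: MouseActivityParams,
    schedule: LightDarkSchedule,
    duration: float,
    geometry: WheelGeometry,
    wall_start: datetime | None = None,
) -> RotationTrace:
    """Generate bout-structured nocturnal running for one cage.

    Rest and run bouts alternate: onsets come from a phase-dependent
    Poisson process (rate = ``dark_bout_rate`` in dark, ``light_bout_rate``
    in light, in bouts/hour), bout durations are gamma, and within a bout
    the wheel turns at ``speed / circumference`` rev/s with equally spaced
    rotations. Fully reproducible from ``params.seed``.
    """
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if wall_start is None:
        wall_start = RotationTrace.__dataclass_fields__["wall_start"].default
    rng = np.random.default_rng(params.seed)
    times: list[np.ndarray] = []
    t = 0.0
    last_rotation = -math.inf
    while True:
        onset = _draw_bout_onset(t, duration, params, schedule, wall_start, rng)
        if onset is None:
            break
        bout_len = rng.gamma(
            params.bout_duration_shape,
            params.bout_duration_mean / params.bout_duration_shape,
        )
        end = min(onset + bout_len, duration)
        speed = max(0.0, rng.normal(params.run_speed_mean, params.run_speed_sd))
        rate = speed / geometry.circumference
        if rate > 0:
            n = int(math.floor((end - onset) * rate + _EPS))
            if n:
                k = np.arange(1, n + 1, dtype=float)
                rot = onset + k / rate
                # guard against float collision with the previous bout's tail
                rot = rot[rot > last_rotation + _EPS]
                if rot.size:
                    times.append(rot)
                    last_rotation = rot[-1]
        t = end
        if t >= duration:
            break
    rotation_times = np.concatenate(times) if times else np.empty(0)
    rotation_times = np.minimum(rotation_times, duration)
    return RotationTrace(rotation_times, duration=duration, wall_start=wall_start)


def trace_total_distance(trace: RotationTrace, geometry: WheelGeometry) -> float:
    """Ground-truth distance in cm: rotation count times circumference."""
    return trace.n_rotations * geometry.circumference


def write_trace_csv(trace: RotationTrace) -> str:
    """Ground-truth trace as two-column CSV text (rotation_index, time_s)."""
    lines = ["rotation_index,time_s"]
    for i, t in enumerate(trace.rotation_times):
        lines.append(f"{i},{t:.6f}")
    return "\n".join(lines) + "\n"
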