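"""Hall-sensor and microcontroller acquisition chain emulator.

A magnet passing the Hall sensor fires one trigger per wheel rotation;
the microcontroller accumulates a cumulative count per sensor and a
logger samples those counts at a fixed rate (the in-silico analogue of a
serial capture at, e.g., 4 Hz). Sampling can only *delay* a count within
one sample period, never lose it — the transient per-sensor misalignment
seen when the rotation period beats against the 0.25 s refresh, which
disappears once rotation and sampling de-phase.

The canonical on-disk dialect stores integer cumulative counts (lossless)
with wheel circumference in the header; a ``distance_cm`` dialect writes
the derived distance instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .simulator import RotationTrace

__all__ = [
    "SensorConfig",
    "SensorEventStream",
    "SerialLog",
    "sense_rotations",
    "sample_counts",
    "write_log",
]

DIALECTS = ("counts", "distance_cm")
LOG_VERSION = "1"


@dataclass(frozen=True)
class SensorConfig:
    """Imperfection knobs for one emulated Hall sensor.

    The default models the sensor the way the hardware behaves in
    practice: exact counting with a short 50 ms refractory period (a wheel
    would have to exceed 20 rev/s to lose a count). ``ideal()`` gives the
    zero-refractory identity configuration used for exactness contracts.
    """

    refractory_ms: float = 50.0
    trigger_jitter_ms: float = 0.0
    miss_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.refractory_ms < 0:
            raise ValueError(f"refractory_ms must be >= 0, got {self.refractory_ms}")
        if self.trigger_jitter_ms < 0:
            raise ValueError("trigger_jitter_ms must be >= 0")
        if not 0 <= self.miss_probability < 1:
            raise ValueError(
                f"miss_probability must be in [0, 1), got {self.miss_probability}"
            )

    @classmethod
    def ideal(cls) -> "SensorConfig":
        return cls(refractory_ms=0.0, trigger_jitter_ms=0.0, miss_probability=0.0)


@dataclass(frozen=True)
class SensorEventStream:
    """Trigger times (s offsets, strictly increasing) for one sensor."""

    sensor_id: str
    trigger_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.trigger_times, dtype=float)
        object.__setattr__(self, "trigger_times", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("trigger_times must be strictly increasing")


@dataclass
class SerialLog:
    """Sampled acquisition record: per-sensor cumulative counts on a fixed grid.

    ``samples`` has shape (n_samples, n_sensors), integer cumulative
    counts; sample ``k`` corresponds to elapsed time ``k * sample_period``.
    ``header_metadata`` carries the geometry (circumference per sensor)
    and any schedule/dialect annotations needed downstream.
    """

    sample_period: float
    wall_start: datetime
    sensor_ids: tuple[str, ...]
    samples: np.ndarray
    dialect: str = "counts"
    header_metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sensor_ids = tuple(self.sensor_ids)
        self.samples = np.asarray(self.samples, dtype=np.int64).reshape(
            -1, len(self.sensor_ids)
        )
        if self.sample_period <= 0:
            raise ValueError("sample_period must be > 0")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_period

    @property
    def duration(self) -> float:
        return max(0, self.n_samples - 1) * self.sample_period

    def is_monotone(self) -> bool:
        return self.n_samples < 2 or bool(np.all(np.diff(self.samples, axis=0) >= 0))

    def circumference_for(self, sensor_id: str) -> float:
        circs = self.header_metadata.get("circumference_cm", "")
        values = [float(v) for v in circs.split(",") if v]
        return values[self.sensor_ids.index(sensor_id)]


def sense_rotations(
    trace: RotationTrace, config: SensorConfig, seed: int = 0, sensor_id: str = "s1"
) -> SensorEventStream:
    """Convert rotations into sensor triggers.

    Each rotation fires one trigger, optionally perturbed by Gaussian
    timing jitter, dropped with ``miss_probability``, and suppressed if it
    falls within the refractory period of the previously kept trigger.
    With the ideal config the trigger times equal the rotation times
    exactly.
    """
    times = trace.rotation_times.copy()
    rng = np.random.default_rng(seed)
    if config.trigger_jitter_ms > 0 and times.size:
        times = times + rng.normal(0.0, config.trigger_jitter_ms / 1000.0, times.size)
        times = np.sort(np.clip(times, 0.0, trace.duration))
    if config.miss_probability > 0 and times.size:
        keep = rng.random(times.size) >= config.miss_probability
        times = times[keep]
    if config.refractory_ms > 0 and times.size:
        refractory = config.refractory_ms / 1000.0
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.array(kept)
    # jitter can create exact duplicates after clipping; thin them
    if times.size > 1:
        keep_mask = np.concatenate(([True], np.diff(times) > 0))
        times = times[keep_mask]
    return SensorEventStream(sensor_id=sensor_id, trigger_times=times)


def sample_counts(
    streams: list[SensorEventStream],
    sample_rate: float,
    duration: float,
    wall_start: datetime,
    dialect: str = "counts",
    header_metadata: dict[str, str] | None = None,
) -> SerialLog:
    """Sample cumulative trigger counts at a fixed rate into a SerialLog.

    Sample ``k`` (at ``t = k / sample_rate``, including t = 0) holds the
    number of triggers with time <= t per sensor — a closed upper bound,
    so a trigger landing exactly on a sample instant is included in that
    sample. The final sample therefore carries every trigger: sampling
    delays counts by at most one period but never drops them.
    """
    if sample_rate <= 0:
        raise ValueError(f"sample_rate must be > 0, got {sample_rate}")
    period = 1.0 / sample_rate
    n_samples = int(math.floor(duration / period + 1e-9)) + 1
    grid = np.arange(n_samples) * period
    counts = np.empty((n_samples, len(streams)), dtype=np.int64)
    for j, stream in enumerate(streams):
        if stream.trigger_times.size and stream.trigger_times[-1] > duration + 1e-9:
            raise ValueError(
                f"sensor {stream.sensor_id!r} has triggers beyond duration {duration}"
            )
        # closed upper bound: trigger at exactly t counts in sample t
        counts[:, j] = np.searchsorted(
            stream.trigger_times, grid + 1e-9, side="right"
        )
        # the logger flushes its counter state on the final line, so any
        # triggers in a trailing partial period are carried by that sample
        counts[-1, j] = stream.trigger_times.size
    meta = dict(header_metadata or {})
    return SerialLog(
        sample_period=period,
        wall_start=wall_start,
        sensor_ids=tuple(s.sensor_id for s in streams),
        samples=counts,
        dialect=dialect,
        header_metadata=meta,
    )


def write_log(log: SerialLog) -> str:
    """Serialise a SerialLog in the canonical text dialect.

    Header lines start with ``#`` and hold ``key=value`` pairs; data lines
    are ``elapsed_ms`` followed by one tab-separated field per sensor
    (integer cumulative counts, or distance in cm for the ``distance_cm``
    dialect). UTF-8, LF line endings.
    """
    lines = [
        f"# version={LOG_VERSION}",
        f"# wall_start={log.wall_start.isoformat()}",
        f"# sample_period_s={log.sample_period!r}",
        f"# sensors={','.join(log.sensor_ids)}",
        f"# dialect={log.dialect}",
    ]
    reserved = {"version", "wall_start", "sample_period_s", "sensors", "dialect"}
    if "circumference_cm" not in log.header_metadata and log.dialect == "distance_cm":
        raise ValueError("distance_cm dialect requires circumference_cm metadata")
    for key, value in log.header_metadata.items():
        if key not in reserved:
            lines.append(f"# {key}={value}")
    if log.dialect == "distance_cm":
        circ = np.array(
            [log.circumference_for(s) for s in log.sensor_ids], dtype=float
        )
    for k in range(log.n_samples):
        elapsed_ms = round(k * log.sample_period * 1000)
        if log.dialect == "counts":
            fields = [str(int(c)) for c in log.samples[k]]
        else:
            fields = [f"{c * circ[j]:.6f}" for j, c in enumerate(log.samples[k])]
        lines.append("\t".join([str(elapsed_ms)] + fields))
    return "\n".join(lines) + "\n"
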