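"""Serial-log parsing, experiment configuration, and quality control.

QC covers the failure modes that actually occur with home-cage wheel
trackers: a wheel jammed by bedding (flatline: a sensor stops counting
while cage-mates keep running), an acquisition restart after cage
service (counter reset: the cumulative column drops), and a sensor that
never appears in the log. QC is advisory — it flags and recommends, it
never mutates or drops data; exclusion is an explicit caller decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time as dtime

import numpy as np
import yaml

from .acquisition import DIALECTS, SerialLog
from .simulator import LightDarkSchedule, WheelGeometry

__all__ = [
    "ExperimentConfig",
    "CageSpec",
    "QCFinding",
    "QCReport",
    "LogParseError",
    "parse_log",
    "detect_counter_resets",
    "qc_scan",
    "load_config",
]

REQUIRED_HEADER_KEYS = ("version", "wall_start", "sample_period_s", "sensors", "dialect")


class LogParseError(ValueError):
    """Malformed serial log; message names the offending line/sample."""


@dataclass(frozen=True)
class CageSpec:
    label: str
    sensor_id: str
    geometry: WheelGeometry
    group_size: int = 1

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment description: cages, light/dark schedule, optional paired design."""

    cages: tuple[CageSpec, ...]
    schedule: LightDarkSchedule
    design: dict | None = None

    def __post_init__(self) -> None:
        sensor_ids = [c.sensor_id for c in self.cages]
        if len(set(sensor_ids)) != len(sensor_ids):
            raise ValueError("sensor_ids must be unique across cages")

    def cage_for_sensor(self, sensor_id: str) -> CageSpec | None:
        for cage in self.cages:
            if cage.sensor_id == sensor_id:
                return cage
        return None


@dataclass(frozen=True)
class QCFinding:
    cage: str
    kind: str  # flatline | counter_reset | missing_sensor
    start_s: float
    end_s: float
    severity: str  # warning | exclude


@dataclass
class QCReport:
    findings: list[QCFinding] = field(default_factory=list)
    excluded_cages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        flagged = {f.cage for f in self.findings}
        for cage in self.excluded_cages:
            if cage not in flagged:
                raise ValueError(f"excluded cage {cage!r} has no finding")

    def to_csv(self) -> str:
        lines = ["cage,kind,start_s,end_s,severity"]
        for f in self.findings:
            lines.append(f"{f.cage},{f.kind},{f.start_s:.3f},{f.end_s:.3f},{f.severity}")
        return "\n".join(lines) + "\n"


def _parse_header(lines: list[str]) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if "=" not in body:
            raise LogParseError(f"line {i + 1}: header line without '=': {line!r}")
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
        i += 1
    return meta, i


def parse_log(text: str, allow_resets: bool = False) -> SerialLog:
    """Parse the canonical serial-log dialect; exact inverse of ``write_log``.

    A decrease in a cumulative column is a parse error naming the sample
    index unless ``allow_resets`` is set, in which case the log is
    returned as-is for :func:`detect_counter_resets` to splice.
    """
    lines = [ln for ln in text.split("\n") if ln != ""]
    meta, first_data = _parse_header(lines)
    for key in REQUIRED_HEADER_KEYS:
        if key not in meta:
            raise LogParseError(f"missing required header key {key!r}")
    dialect = meta["dialect"]
    if dialect not in DIALECTS:
        raise LogParseError(f"unknown dialect {dialect!r}")
    sensor_ids = tuple(s for s in meta["sensors"].split(",") if s)
    sample_period = float(meta["sample_period_s"])
    wall_start = datetime.fromisoformat(meta["wall_start"])
    if dialect == "distance_cm":
        if "circumference_cm" not in meta:
            raise LogParseError("distance_cm dialect requires circumference_cm header")
        circ = np.array([float(v) for v in meta["circumference_cm"].split(",")])
        if circ.size == 1:
            circ = np.repeat(circ, len(sensor_ids))

    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[first_data:], start=first_data + 1):
        fields = line.split("\t")
        if len(fields) != 1 + len(sensor_ids):
            raise LogParseError(
                f"line {lineno}: expected {1 + len(sensor_ids)} fields, got {len(fields)}"
            )
        try:
            elapsed_ms = int(fields[0])
            if dialect == "counts":
                row = [int(f) for f in fields[1:]]
            else:
                row = [
                    int(round(float(f) / circ[j])) for j, f in enumerate(fields[1:])
                ]
        except ValueError as exc:
            raise LogParseError(f"line {lineno}: bad numeric field ({exc})") from None
        expected_ms = round(len(rows) * sample_period * 1000)
        if elapsed_ms != expected_ms:
            raise LogParseError(
                f"line {lineno}: elapsed_ms {elapsed_ms} != expected {expected_ms}"
            )
        rows.append(row)

    samples = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.empty((0, len(sensor_ids)), dtype=np.int64)
    )
    if not allow_resets and samples.shape[0] > 1:
        drops = np.diff(samples, axis=0) < 0
        if drops.any():
            k = int(np.argwhere(drops.any(axis=1))[0, 0]) + 1
            raise LogParseError(
                f"cumulative count decreases at sample index {k}; "
                "re-parse with allow_resets=True and run detect_counter_resets"
            )
    extra = {k: v for k, v in meta.items() if k not in REQUIRED_HEADER_KEYS}
    return SerialLog(
        sample_period=sample_period,
        wall_start=wall_start,
        sensor_ids=sensor_ids,
        samples=samples,
        dialect=dialect,
        header_metadata=extra,
    )


def detect_counter_resets(log: SerialLog) -> SerialLog:
    """Splice acquisition restarts so cumulative totals carry across.

    Any decrease in a cumulative column is read as a counter restart from
    zero: the value after the drop counts rotations since the restart, so
    subsequent samples are re-based by the pre-drop value. Output columns
    are always monotone and total increments are preserved.
    """
    samples = log.samples.copy()
    for j in range(samples.shape[1]):
        col = samples[:, j]
        base = 0
        out = np.empty_like(col)
        out[0] = col[0] if col.size else 0
        for k in range(1, col.size):
            if col[k] < col[k - 1]:
                base += col[k - 1]
            out[k] = base + col[k]
        if col.size:
            out[0] = col[0]
            samples[:, j] = out
    return SerialLog(
        sample_period=log.sample_period,
        wall_start=log.wall_start,
        sensor_ids=log.sensor_ids,
        samples=samples,
        dialect=log.dialect,
        header_metadata=dict(log.header_metadata),
    )


def _zero_runs(increments: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero increments as (start_sample, end_sample) pairs."""
    runs = []
    start = None
    for k, v in enumerate(increments):
        if v == 0 and start is None:
            start = k
        elif v != 0 and start is not None:
            runs.append((start, k))
            start = None
    if start is not None:
        runs.append((start, len(increments)))
    return runs


def qc_scan(
    log: SerialLog,
    config: ExperimentConfig,
    flatline_window: float = 7200.0,
    dark_only: bool = True,
) -> QCReport:
    """Scan a log for jammed wheels, counter resets, and missing sensors.

    A flatline is >= ``flatline_window`` seconds of zero count increase
    (during the dark phase when ``dark_only``) while at least one other
    sensor accumulates counts over the same interval — the signature of a
    wheel physically blocked by bedding. With no comparator sensor the
    finding is downgraded to a warning. Read-only: never mutates the log.
    """
    findings: list[QCFinding] = []
    period = log.sample_period
    times = log.times
    increments = np.diff(log.samples, axis=0) if log.n_samples > 1 else np.empty(
        (0, len(log.sensor_ids)), dtype=np.int64
    )

    present = set(log.sensor_ids)
    for cage in config.cages:
        if cage.sensor_id not in present:
            findings.append(
                QCFinding(cage.label, "missing_sensor", 0.0, log.duration, "exclude")
            )

    # counter resets in the raw (unspliced) log
    for j, sid in enumerate(log.sensor_ids):
        cage = config.cage_for_sensor(sid)
        label = cage.label if cage else sid
        drops = np.where(increments[:, j] < 0)[0]
        for k in drops:
            t = times[k + 1]
            findings.append(QCFinding(label, "counter_reset", t, t, "warning"))

    if log.n_samples > 1:
        dark = (
            config.schedule.phase_array(times[1:], log.wall_start) == "dark"
        )  # phase of each increment's end sample
        inc = np.where(increments < 0, 0, increments)  # resets don't hide flatlines
        for j, sid in enumerate(log.sensor_ids):
            cage = config.cage_for_sensor(sid)
            label = cage.label if cage else sid
            for start, end in _zero_runs(inc[:, j]):
                span = (end - start) * period
                if span < flatline_window:
                    continue
                if dark_only and not dark[start:end].any():
                    continue
                others_active = (
                    np.delete(inc[start:end], j, axis=1).sum() > 0
                    if len(log.sensor_ids) > 1
                    else False
                )
                severity = "exclude" if others_active else "warning"
                findings.append(
                    QCFinding(label, "flatline", times[start], times[end], severity)
                )

    excluded = sorted({f.cage for f in findings if f.severity == "exclude"})
    return QCReport(findings=findings, excluded_cages=excluded)


def _parse_clock(value) -> dtime:
    if isinstance(value, dtime):
        return value
    if isinstance(value, int):  # yaml may read 18:00 as sexagesimal int 1080
        return dtime(value // 60 % 24, value % 60)
    h, _, m = str(value).partition(":")
    return dtime(int(h), int(m or 0))


def load_config(text: str) -> ExperimentConfig:
    """Load an ExperimentConfig from YAML text.

    Expected structure::

        schedule: {dark_onset: "18:00", dark_offset: "06:00"}
        cages:
          cage1: {sensor_id: s1, diameter_cm: 15.9, circumference_cm: 50.0,
                  group_size: 3}
        design:              # optional paired before/after description
          before: baseline
          after: restriction
    """
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "cages" not in raw:
        raise ValueError("config must be a mapping with a 'cages' section")
    sched_raw = raw.get("schedule", {})
    schedule = LightDarkSchedule(
        dark_onset=_parse_clock(sched_raw.get("dark_onset", "18:00")),
        dark_offset=_parse_clock(sched_raw.get("dark_offset", "06:00")),
    )
    cages = []
    for label, spec in raw["cages"].items():
        if "diameter_cm" not in spec:
            raise ValueError(f"cage {label!r}: diameter_cm is required")
        geometry = WheelGeometry(
            magnet_path_diameter=float(spec["diameter_cm"]),
            circumference=(
                float(spec["circumference_cm"]) if "circumference_cm" in spec else None
            ),
        )
        cages.append(
            CageSpec(
                label=str(label),
                sensor_id=str(spec["sensor_id"]),
                geometry=geometry,
                group_size=int(spec.get("group_size", 1)),
            )
        )
    return ExperimentConfig(
        cages=tuple(cages), schedule=schedule, design=raw.get("design")
    )
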