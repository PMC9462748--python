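"""Log parsing, counter-reset splicing, QC, and config loading."""

from datetime import datetime, time

import numpy as np
import pytest

from wheeltrack import (
    CageSpec,
    ExperimentConfig,
    LightDarkSchedule,
    LogParseError,
    SerialLog,
    WheelGeometry,
    detect_counter_resets,
    load_config,
    parse_log,
    qc_scan,
)
from wheeltrack.acquisition import write_log

WALL = datetime(2026, 1, 1, 18, 0, 0)  # dark onset


def make_log(columns, sample_period=0.25, wall_start=WALL):
    samples = np.column_stack(columns)
    return SerialLog(
        sample_period=sample_period,
        wall_start=wall_start,
        sensor_ids=tuple(f"s{i + 1}" for i in range(len(columns))),
        samples=samples,
        header_metadata={"circumference_cm": ",".join(["50.0"] * len(columns))},
    )


def make_config(n_cages=2, schedule=None):
    geo = WheelGeometry(15.9, circumference=50.0)
    cages = tuple(
        CageSpec(label=f"cage{i + 1}", sensor_id=f"s{i + 1}", geometry=geo, group_size=3)
        for i in range(n_cages)
    )
    return ExperimentConfig(cages=cages, schedule=schedule or LightDarkSchedule())


class TestParseLog:
    def test_round_trip(self):
        log = make_log([[0, 1, 3, 3, 7]])
        back = parse_log(write_log(log))
        assert np.array_equal(back.samples, log.samples)
        assert back.header_metadata["circumference_cm"] == "50.0"

    def test_decreasing_count_names_sample_index(self):
        log = make_log([[0, 5, 9, 2, 6]])
        text = write_log(log)
        with pytest.raises(LogParseError, match="sample index 3"):
            parse_log(text)
        # opt-in path for logs containing acquisition restarts
        raw = parse_log(text, allow_resets=True)
        assert np.array_equal(raw.samples[:, 0], [0, 5, 9, 2, 6])

    def test_header_only_gives_empty_log(self):
        log = make_log([[]])
        log.samples = log.samples.reshape(0, 1)
        back = parse_log(write_log(log))
        assert back.n_samples == 0
        assert back.sensor_ids == ("s1",)
        assert back.header_metadata["circumference_cm"] == "50.0"

    def test_missing_header_key_rejected(self):
        text = write_log(make_log([[0, 1]]))
        stripped = "\n".join(
            ln for ln in text.split("\n") if not ln.startswith("# dialect")
        )
        with pytest.raises(LogParseError, match="dialect"):
            parse_log(stripped)

    def test_malformed_line_cites_line_number(self):
        text = write_log(make_log([[0, 1, 2]]))
        lines = text.strip().split("\n")
        lines[-1] = lines[-1] + "\textra"
        with pytest.raises(LogParseError, match=rf"line {len(lines)}"):
            parse_log("\n".join(lines))


class TestCounterResets:
    def test_hand_splice(self):
        log = make_log([[0, 5, 9, 2, 6]])
        fixed = detect_counter_resets(log)
        assert np.array_equal(fixed.samples[:, 0], [0, 5, 9, 11, 15])

    def test_monotone_column_unchanged(self):
        log = make_log([[0, 1, 4, 4, 9]])
        fixed = detect_counter_resets(log)
        assert np.array_equal(fixed.samples, log.samples)

    def test_reset_at_final_sample(self):
        log = make_log([[0, 5, 2]])
        fixed = detect_counter_resets(log)
        assert np.array_equal(fixed.samples[:, 0], [0, 5, 7])

    def test_output_monotone_and_increments_preserved(self):
        rng = np.random.default_rng(5)
        col = [0]
        for _ in range(60):
            col.append(col[-1] + int(rng.integers(0, 4)))
        col = np.array(col)
        # inject two restarts: counter drops to a fresh small value
        broken = col.copy()
        broken[20:] = col[20:] - col[19]
        broken[45:] = broken[45:] - broken[44]
        fixed = detect_counter_resets(make_log([broken]))
        out = fixed.samples[:, 0]
        assert np.all(np.diff(out) >= 0)
        assert out[-1] == col[-1]  # total increments preserved

    def test_does_not_mutate_input(self):
        log = make_log([[0, 5, 2]])
        before = log.samples.copy()
        detect_counter_resets(log)
        assert np.array_equal(log.samples, before)


class TestQCScan:
    def test_all_active_no_findings(self):
        log = make_log([np.arange(100), np.arange(100) * 2])
        report = qc_scan(log, make_config(2), flatline_window=5.0)
        assert report.findings == []
        assert report.excluded_cages == []

    def test_frozen_sensor_flagged_for_exclusion(self):
        # one wheel jams mid-night while the other keeps turning
        n = 200
        active = np.arange(n)
        frozen = np.minimum(np.arange(n), 80)
        log = make_log([active, frozen], sample_period=60.0)
        report = qc_scan(log, make_config(2), flatline_window=3600.0)
        flat = [f for f in report.findings if f.kind == "flatline"]
        assert len(flat) == 1
        assert flat[0].cage == "cage2"
        assert flat[0].severity == "exclude"
        assert flat[0].start_s <= 81 * 60.0 <= flat[0].end_s or flat[0].start_s >= 80 * 60.0
        assert report.excluded_cages == ["cage2"]

    def test_single_sensor_flatline_is_warning_only(self):
        frozen = np.minimum(np.arange(200), 50)
        log = make_log([frozen], sample_period=60.0)
        report = qc_scan(log, make_config(1), flatline_window=3600.0)
        flat = [f for f in report.findings if f.kind == "flatline"]
        assert len(flat) == 1
        assert flat[0].severity == "warning"
        assert report.excluded_cages == []

    def test_light_phase_flatline_ignored_when_dark_only(self):
        light_start = datetime(2026, 1, 1, 6, 0, 0)
        frozen = np.zeros(200, dtype=int)
        active = np.arange(200)
        log = make_log([active, frozen], sample_period=60.0, wall_start=light_start)
        report = qc_scan(log, make_config(2), flatline_window=3600.0, dark_only=True)
        assert [f for f in report.findings if f.kind == "flatline"] == []

    def test_missing_sensor_reported(self):
        log = make_log([np.arange(10)])
        report = qc_scan(log, make_config(2), flatline_window=1.0)
        missing = [f for f in report.findings if f.kind == "missing_sensor"]
        assert [f.cage for f in missing] == ["cage2"]

    def test_counter_reset_finding_on_raw_log(self):
        log = make_log([[0, 5, 2, 6]])
        report = qc_scan(log, make_config(1), flatline_window=1e9)
        resets = [f for f in report.findings if f.kind == "counter_reset"]
        assert len(resets) == 1

    def test_scan_is_read_only_and_idempotent(self):
        frozen = np.minimum(np.arange(200), 80)
        log = make_log([np.arange(200), frozen], sample_period=60.0)
        before = log.samples.copy()
        r1 = qc_scan(log, make_config(2), flatline_window=3600.0)
        r2 = qc_scan(log, make_config(2), flatline_window=3600.0)
        assert np.array_equal(log.samples, before)
        assert r1.findings == r2.findings


class TestConfig:
    CONFIG_TEXT = """
schedule:
  dark_onset: "18:00"
  dark_offset: "06:00"
cages:
  cage1: {sensor_id: s1, diameter_cm: 15.9, circumference_cm: 50.0, group_size: 3}
  cage2: {sensor_id: s2, diameter_cm: 16.0}
design:
  before: baseline
  after: restriction
"""

    def test_load_config_full(self):
        cfg = load_config(self.CONFIG_TEXT)
        assert len(cfg.cages) == 2
        assert cfg.cages[0].geometry.circumference == 50.0
        assert cfg.cages[0].group_size == 3
        assert cfg.schedule.dark_onset == time(18, 0)
        assert cfg.design == {"before": "baseline", "after": "restriction"}

    def test_duplicate_sensor_ids_rejected(self):
        text = self.CONFIG_TEXT.replace("sensor_id: s2", "sensor_id: s1")
        with pytest.raises(ValueError, match="unique"):
            load_config(text)

    def test_missing_diameter_rejected(self):
        text = self.CONFIG_TEXT.replace("diameter_cm: 16.0", "group_size: 1")
        with pytest.raises(ValueError, match="diameter_cm"):
            load_config(text)
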