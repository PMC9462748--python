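from datetime import datetime

import pytest

from wheeltrack import (
    LightDarkSchedule,
    SensorConfig,
    SpeedProfile,
    WheelGeometry,
    sample_counts,
    sense_rotations,
    simulate_robotic_run,
)

#: fixture wheel: 15.9 cm disc calibrated to a round 50 cm circumference
FIXTURE_DIAMETER = 15.9
FIXTURE_CIRCUMFERENCE = 50.0


@pytest.fixture
def geometry():
    return WheelGeometry(FIXTURE_DIAMETER, circumference=FIXTURE_CIRCUMFERENCE)


@pytest.fixture
def schedule():
    # standard vivarium 12 h/12 h cycle, dark 18:00-06:00
    return LightDarkSchedule()


@pytest.fixture
def mechanical_profile():
    """Three constant-speed run intervals separated by pauses, 85 s total."""
    return SpeedProfile([(15, 0.89), (10, 0.0), (15, 0.89), (10, 0.0), (35, 0.89)])


@pytest.fixture
def mechanical_trace(mechanical_profile, geometry):
    return simulate_robotic_run(
        mechanical_profile, geometry, wall_start=datetime(2026, 1, 1, 10, 0, 0)
    )


@pytest.fixture
def mechanical_log(mechanical_trace):
    """Five ideal sensors on the same wheel, sampled at 4 Hz for 85 s."""
    streams = [
        sense_rotations(mechanical_trace, SensorConfig.ideal(), sensor_id=f"s{i + 1}")
        for i in range(5)
    ]
    circs = ",".join(["50.0"] * 5)
    return sample_counts(
        streams,
        sample_rate=4.0,
        duration=mechanical_trace.duration,
        wall_start=mechanical_trace.wall_start,
        header_metadata={"circumference_cm": circs},
    )
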