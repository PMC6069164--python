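import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fallsense.config import PipelineConfig
from fallsense.detector import run_detector
from fallsense.simulator import (
    GAIT_PRESETS,
    MotionScript,
    Segment,
    simulate,
    standard_suite,
)

#: one fixed seed for the reproducible end-to-end benchmark used by the
#: acceptance tests; any seed gives the same qualitative behaviour
SUITE_SEED = 42


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def fall_stream():
    """Walk, fall forward (1.9 s), then lie still."""
    script = MotionScript(
        segments=(
            Segment("walk", 2.5),
            Segment("fall_forward", 1.9),
            Segment("lie_floor", 3.0),
        ),
        gait=GAIT_PRESETS["normal"],
        seed=5,
    )
    return simulate(script)


@pytest.fixture(scope="session")
def adl_stream():
    """Walk, sit on a chair, then lie down slowly — no fall."""
    script = MotionScript(
        segments=(
            Segment("walk", 2.5),
            Segment("sit_chair", 3.0, {"transition": 2.0}),
            Segment("lie_floor", 7.0, {"transition": 3.85}),
        ),
        gait=GAIT_PRESETS["normal"],
        seed=11,
    )
    return simulate(script)


@pytest.fixture(scope="session")
def suite_results(config):
    """The standard 30-fall / 40-ADL suite, detected once and shared by
    the end-to-end tests."""
    sequences = standard_suite(SUITE_SEED)
    labels, events = {}, {}
    for i, (stream, label_df) in enumerate(sequences):
        seq_id = f"seq{i:03d}_{stream.metadata['scenario']}"
        labels[seq_id] = bool(stream.metadata["is_fall_sequence"])
        events[seq_id] = run_detector(stream, config)
    return labels, events
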