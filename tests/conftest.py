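import numpy as np
import pytest

from gaitstate.io import GrfRecording, SensorLayout, StateSeries, Subject


@pytest.fixture
def layout() -> SensorLayout:
    return SensorLayout.default()


@pytest.fixture
def subject() -> Subject:
    return Subject(height=1.75, weight=68.0, group="healthy")


@pytest.fixture
def make_recording(layout, subject):
    """Factory for small recordings with explicit force matrices."""

    def _make(forces, sampling_rate=100.0, triggers=None):
        forces = np.asarray(forces, dtype=float)
        return GrfRecording(
            sampling_rate=sampling_rate,
            forces=forces,
            layout=layout,
            subject=subject,
            trigger_marks=triggers if triggers is not None else (0, len(forces)),
        )

    return _make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_states(values, rate=100.0) -> StateSeries:
    return StateSeries(sampling_rate=rate, states=np.asarray(values))
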