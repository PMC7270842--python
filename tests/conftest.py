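from datetime import datetime, timedelta

import pytest

from alarmfap import (
    AlarmContext,
    ArtifactCause,
    PatientProfile,
    ReasonerParams,
    RunConfig,
    VitalReading,
    Vital,
    build_context,
)

NOW = datetime(2019, 7, 2, 21, 51, 6, 291000)


@pytest.fixture
def params() -> ReasonerParams:
    return ReasonerParams()


@pytest.fixture
def patient_one() -> PatientProfile:
    return PatientProfile(1, 1, 35.5, 39.0, 60, 100)


@pytest.fixture
def patient_two() -> PatientProfile:
    return PatientProfile(2, 1, 35.0, 38.5, 55, 95)


@pytest.fixture
def clean_context() -> AlarmContext:
    return build_context(NOW, frozenset())


def make_context(*causes: ArtifactCause, at: datetime = NOW) -> AlarmContext:
    return build_context(at, frozenset(causes))


def make_reading(
    patient_id: int = 1,
    vital: Vital = Vital.TEMPERATURE,
    value: float = 37.0,
    at: datetime = NOW,
) -> VitalReading:
    return VitalReading(patient_id, vital, value, at)


@pytest.fixture
def small_run_config() -> RunConfig:
    """A short but fully featured run used by pipeline-level tests."""
    import dataclasses

    config = RunConfig()
    return dataclasses.replace(
        config,
        simulation=dataclasses.replace(config.simulation, duration=240.0, seed=3),
    )


def ts(seconds: float) -> datetime:
    return NOW + timedelta(seconds=seconds)
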