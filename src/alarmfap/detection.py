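"""Threshold-alarm detection.

Screens each vital reading against the patient's per-vital anomaly
thresholds and mints alarm events with sequential IDs.  Thresholds are
inclusive-normal: only values strictly below the minimum or strictly above
the maximum raise an alarm, and every anomalous reading is its own alarm
(no hysteresis or de-duplication of sustained violations).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime

from .errors import ConfigError
from .reasoner import FAIVector
from .simulator import AlarmContext, PatientProfile, Vital, VitalReading


class Direction(str, enum.Enum):
    LOW = "LOW"
    HIGH = "HIGH"


@dataclass(frozen=True)
class AlarmEvent:
    """A single threshold violation with its context snapshot.

    ``fai_vector`` and ``fap`` are unset at mint time and filled by the
    reasoner.
    """

    alarm_id: int
    ward_id: int
    patient_id: int
    vital: Vital
    sensor_value: float
    alarm_timestamp: datetime
    direction: Direction
    context: AlarmContext
    fai_vector: FAIVector | None = None
    fap: float | None = None


def detect_anomaly(reading: VitalReading, profile: PatientProfile) -> Direction | None:
    """Return LOW/HIGH if the reading strictly violates a threshold, else None.

    Values exactly equal to a threshold are considered normal.
    """
    if reading.patient_id != profile.patient_id:
        raise ConfigError(
            f"reading for patient {reading.patient_id} screened against "
            f"profile of patient {profile.patient_id}"
        )
    lo, hi = profile.thresholds(reading.vital)
    if reading.value < lo:
        return Direction.LOW
    if reading.value > hi:
        return Direction.HIGH
    return None


class AlarmCounter:
    """Sequential alarm-ID source, one counter per (ward, vital) stream.

    A ward's temperature and heart-rate alarms are numbered independently,
    each from 1, and the counter is shared across patients — interleaved
    alarms from different patients therefore show per-patient gaps.
    """

    def __init__(self) -> None:
        self._next: dict[tuple[int, Vital], int] = {}

    def next_id(self, ward_id: int, vital: Vital) -> int:
        key = (ward_id, vital)
        aid = self._next.get(key, 1)
        self._next[key] = aid + 1
        return aid


def mint_alarm(
    reading: VitalReading,
    direction: Direction,
    context: AlarmContext,
    counter: AlarmCounter,
    ward_id: int,
) -> AlarmEvent:
    """Create an AlarmEvent with the next sequential ID for its stream."""
    return AlarmEvent(
        alarm_id=counter.next_id(ward_id, reading.vital),
        ward_id=ward_id,
        patient_id=reading.patient_id,
        vital=reading.vital,
        sensor_value=reading.value,
        alarm_timestamp=reading.timestamp,
        direction=direction,
        context=context,
    )
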