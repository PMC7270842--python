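"""Seeded ICU vital-sign and alarm-context simulator.

Emits uniform-random temperature (35.0–42.0 °C at 0.1 °C resolution) and
heart-rate (40–188 integer BPM) readings on a fixed per-patient cadence,
together with per-reading snapshots of the eight alarm-context inputs the
reasoner consumes (battery charge and change time, skin-preparation and
electrode-change times, patient localization and its log, bed position and
its log).

Artifact events — the situations that cause technical false alarms — are
injected as independent Poisson processes, one per false-alarm cause, each
holding its context feature in the activating state for a configurable
duration.  The injected cause set is recorded per snapshot as hidden ground
truth so that labelling decisions can be scored downstream; the reasoner
itself never reads it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

from .errors import ConfigError

#: Simulation epoch; chosen to make short demo runs line up with the
#: worked-example notification tables bundled with the package.
DEFAULT_START_TIME = datetime(2019, 7, 2, 21, 51, 0)

#: Location / bed-position labels used by the context generator.
BED_LOCATION = "bed"
AWAY_LOCATION = "corridor"
BASE_POSITION = "supine"
ALT_POSITION = "lateral"


class Vital(str, enum.Enum):
    """A monitored vital sign."""

    TEMPERATURE = "TEMPERATURE"
    HEART_RATE = "HEART_RATE"


class ArtifactCause(str, enum.Enum):
    """Ground-truth cause of an artifact (technically induced) alarm.

    Each cause maps one-to-one onto a false-alarm indicator: low/stale
    battery, degraded sensor placement, patient mobility away from bed,
    and patient repositioning in bed.
    """

    BATTERY = "BATTERY"
    PLACEMENT = "PLACEMENT"
    MOBILITY = "MOBILITY"
    REPOSITIONING = "REPOSITIONING"


@dataclass(frozen=True)
class PatientProfile:
    """Identity plus per-vital anomaly thresholds for one patient.

    Readings strictly below the minimum or strictly above the maximum
    threshold trigger an alarm; values equal to a threshold are normal.
    """

    patient_id: int
    ward_id: int
    min_temp: float
    max_temp: float
    min_hr: float
    max_hr: float

    def __post_init__(self) -> None:
        if self.patient_id <= 0 or self.ward_id <= 0:
            raise ConfigError("patient_id and ward_id must be positive")
        if not self.min_temp < self.max_temp:
            raise ConfigError(
                f"patient {self.patient_id}: min_temp must be < max_temp"
            )
        if not self.min_hr < self.max_hr:
            raise ConfigError(
                f"patient {self.patient_id}: min_hr must be < max_hr"
            )

    def thresholds(self, vital: Vital) -> tuple[float, float]:
        if vital is Vital.TEMPERATURE:
            return self.min_temp, self.max_temp
        if vital is Vital.HEART_RATE:
            return self.min_hr, self.max_hr
        raise ConfigError(f"no thresholds configured for vital {vital!r}")


#: Anomaly thresholds of the four-patient ward used throughout the
#: worked examples (temperature in °C, heart rate in BPM).
DEFAULT_PATIENTS: tuple[PatientProfile, ...] = (
    PatientProfile(1, 1, 35.5, 39.0, 60, 100),
    PatientProfile(2, 1, 35.0, 38.5, 55, 95),
    PatientProfile(3, 1, 35.5, 39.5, 60, 100),
    PatientProfile(4, 1, 35.5, 38.5, 50, 100),
)

#: Default artifact-event rate, events/hour per cause per patient.  With the
#: default 120 s hold this keeps each cause active roughly a third of the
#: time, producing the broad mix of FAP levels seen in a busy ward.
DEFAULT_ARTIFACT_RATE = 12.0


def _default_rates() -> dict[ArtifactCause, float]:
    return {cause: DEFAULT_ARTIFACT_RATE for cause in ArtifactCause}


@dataclass
class SimulationConfig:
    """Parameters of one simulated monitoring run.

    ``reading_interval`` and ``duration`` are in seconds; ``artifact_rates``
    are Poisson event rates in events/hour per cause; ``artifact_hold`` is
    the time in seconds each injected cause stays active.
    """

    ward_id: int = 1
    patients: tuple[PatientProfile, ...] = DEFAULT_PATIENTS
    temp_range: tuple[float, float] = (35.0, 42.0)
    hr_range: tuple[int, int] = (40, 188)
    reading_interval: float = 2.0
    duration: float = 600.0
    artifact_rates: dict[ArtifactCause, float] = field(default_factory=_default_rates)
    artifact_hold: float = 120.0
    start_time: datetime = DEFAULT_START_TIME
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.patients:
            raise ConfigError("patients must be non-empty")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ConfigError("patient_id values must be unique within the ward")
        if not self.temp_range[0] < self.temp_range[1]:
            raise ConfigError("temp_range must satisfy min < max")
        if not self.hr_range[0] < self.hr_range[1]:
            raise ConfigError("hr_range must satisfy min < max")
        if self.reading_interval <= 0:
            raise ConfigError("reading_interval must be positive")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.artifact_hold <= 0:
            raise ConfigError("artifact_hold must be positive")
        for cause, rate in self.artifact_rates.items():
            if rate < 0:
                raise ConfigError(f"artifact rate for {cause} must be >= 0")

    @property
    def n_readings(self) -> int:
        """Readings per patient per vital over the run."""
        return int(self.duration // self.reading_interval)


@dataclass(frozen=True)
class VitalReading:
    """One timestamped sensor value for one patient and vital type."""

    patient_id: int
    vital: Vital
    value: float
    timestamp: datetime


@dataclass(frozen=True)
class AlarmContext:
    """Snapshot of the eight alarm-context inputs at one instant.

    ``truth_artifact_causes`` is simulator-only ground truth (the causes
    injected and active at the snapshot time); it is ``None`` for contexts
    reconstructed from recorded data, and the reasoner never consults it.
    """

    level_of_battery: float | None
    last_time_battery_changed: datetime | None
    last_time_skin_preparation: datetime | None
    last_time_electrodes_changed: datetime | None
    current_patient_localization: str | None
    log_last_patient_localization: tuple[tuple[datetime, str], ...]
    current_patient_position_in_bed: str | None
    log_last_patient_positions_in_bed: tuple[tuple[datetime, str], ...]
    truth_artifact_causes: frozenset[ArtifactCause] | None = None


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent child generator so streams do not perturb each other."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


_VITAL_KEY = {Vital.TEMPERATURE: 0, Vital.HEART_RATE: 1}
_CAUSE_KEY = {c: 100 + i for i, c in enumerate(ArtifactCause)}


def simulate_vitals(config: SimulationConfig) -> list[VitalReading]:
    """Generate the time-ordered stream of vital readings for a run.

    One reading per patient per vital per ``reading_interval``.  Temperature
    is uniform over ``temp_range`` at 0.1 °C resolution; heart rate is
    uniform over the integers of ``hr_range`` (both ranges closed).
    Identical config and seed yield an identical stream.
    """
    n = config.n_readings
    t_lo = int(round(config.temp_range[0] * 10))
    t_hi = int(round(config.temp_range[1] * 10))
    readings: list[VitalReading] = []
    for patient in config.patients:
        times = [
            config.start_time + timedelta(seconds=k * config.reading_interval)
            for k in range(n)
        ]
        rng_t = _stream(config.seed, patient.patient_id, _VITAL_KEY[Vital.TEMPERATURE])
        temps = rng_t.integers(t_lo, t_hi + 1, size=n) / 10.0
        rng_h = _stream(config.seed, patient.patient_id, _VITAL_KEY[Vital.HEART_RATE])
        rates = rng_h.integers(config.hr_range[0], config.hr_range[1] + 1, size=n)
        for ts, temp, hr in zip(times, temps, rates):
            readings.append(
                VitalReading(patient.patient_id, Vital.TEMPERATURE, float(temp), ts)
            )
            readings.append(
                VitalReading(patient.patient_id, Vital.HEART_RATE, float(hr), ts)
            )
    readings.sort(key=lambda r: (r.timestamp, r.patient_id, r.vital.value))
    return readings


def _arrivals(
    rng: np.random.Generator, rate_per_hour: float, duration: float, hold: float
) -> list[float]:
    """Poisson arrival offsets (seconds) over [-hold, duration).

    Starting one hold before the run makes cause activity stationary from
    the first reading instead of ramping up from an artificially clean
    start.
    """
    if rate_per_hour <= 0:
        return []
    out: list[float] = []
    t = -hold + rng.exponential(3600.0 / rate_per_hour)
    while t < duration:
        out.append(t)
        t += rng.exponential(3600.0 / rate_per_hour)
    return out


def _active_causes(
    offset: float, windows: dict[ArtifactCause, list[float]], hold: float
) -> frozenset[ArtifactCause]:
    active = {
        cause
        for cause, starts in windows.items()
        if any(a <= offset < a + hold for a in starts)
    }
    return frozenset(active)


def build_context(at: datetime, causes: frozenset[ArtifactCause]) -> AlarmContext:
    """Construct a context snapshot whose features activate exactly `causes`.

    The clean baseline has a full, recently changed battery, skin prepared
    and electrodes changed two hours ago, the patient in bed with a stable
    localization log, and a stable bed position.  Each injected cause moves
    only its own feature into the activating state.
    """
    battery = 10.0 if ArtifactCause.BATTERY in causes else 95.0
    electrodes = at - (
        timedelta(hours=48) if ArtifactCause.PLACEMENT in causes else timedelta(hours=2)
    )
    localization = AWAY_LOCATION if ArtifactCause.MOBILITY in causes else BED_LOCATION
    if ArtifactCause.REPOSITIONING in causes:
        position_log = (
            (at - timedelta(seconds=30), BASE_POSITION),
            (at - timedelta(seconds=10), ALT_POSITION),
        )
    else:
        position_log = ((at - timedelta(seconds=30), BASE_POSITION),)
    return AlarmContext(
        level_of_battery=battery,
        last_time_battery_changed=at - timedelta(hours=1),
        last_time_skin_preparation=at - timedelta(hours=2),
        last_time_electrodes_changed=electrodes,
        current_patient_localization=localization,
        log_last_patient_localization=((at - timedelta(seconds=30), BED_LOCATION),),
        current_patient_position_in_bed=BASE_POSITION,
        log_last_patient_positions_in_bed=position_log,
        truth_artifact_causes=causes,
    )


def simulate_context(
    config: SimulationConfig, vitals: list[VitalReading]
) -> dict[tuple[int, datetime], AlarmContext]:
    """Context snapshot per (patient, reading time), with injected artifacts.

    Artifact events arrive per cause and patient as independent Poisson
    processes at ``config.artifact_rates`` and hold their feature active for
    ``config.artifact_hold`` seconds.  Deterministic under the config seed.
    """
    times_by_patient: dict[int, set[datetime]] = {}
    for r in vitals:
        times_by_patient.setdefault(r.patient_id, set()).add(r.timestamp)

    snapshots: dict[tuple[int, datetime], AlarmContext] = {}
    for patient in config.patients:
        pid = patient.patient_id
        windows = {
            cause: _arrivals(
                _stream(config.seed, pid, _CAUSE_KEY[cause]),
                config.artifact_rates.get(cause, 0.0),
                config.duration,
                config.artifact_hold,
            )
            for cause in ArtifactCause
        }
        for ts in sorted(times_by_patient.get(pid, ())):
            offset = (ts - config.start_time).total_seconds()
            causes = _active_causes(offset, windows, config.artifact_hold)
            snapshots[(pid, ts)] = build_context(ts, causes)
    return snapshots
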