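"""Run configuration: YAML/JSON loading with validation and full defaults.

An empty or absent file yields the default study conditions: the bundled
four-patient threshold table, temperature simulated in 35.0–42.0 °C, heart
rate in 40–188 BPM, equal indicator weights, FAP_NOT_MIN 75%, and a 300 s
batching window.  Every schema violation is reported with the offending
key's name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import yaml

from .errors import ConfigError
from .reasoner import ReasonerParams
from .simulator import (
    DEFAULT_START_TIME,
    ArtifactCause,
    PatientProfile,
    SimulationConfig,
)

_SIM_KEYS = {
    "ward_id",
    "patients",
    "temp_range",
    "hr_range",
    "reading_interval",
    "duration",
    "artifact_rates",
    "artifact_hold",
    "start_time",
    "seed",
}
_TOP_KEYS = _SIM_KEYS | {"reasoner", "window"}
_REASONER_KEYS = {
    "weights",
    "fap_not_min",
    "battery_low_threshold",
    "battery_life",
    "skin_prep_max_age",
    "electrode_max_age",
    "mobility_window",
    "repositioning_window",
    "bed_location",
}
_PATIENT_KEYS = {"patient_id", "ward_id", "min_temp", "max_temp", "min_hr", "max_hr"}


@dataclass
class RunConfig:
    """Everything one pipeline run needs: simulator, reasoner, batching."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reasoner: ReasonerParams = field(default_factory=ReasonerParams)
    window: float = 300.0

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ConfigError("window must be positive")


def _check_keys(mapping: dict, allowed: set[str], scope: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown configuration key {scope}{key!r}")


def _parse_patients(raw: list, ward_id: int) -> tuple[PatientProfile, ...]:
    if not isinstance(raw, list) or not raw:
        raise ConfigError("'patients' must be a non-empty list of mappings")
    patients = []
    for entry in raw:
        if not isinstance(entry, dict):
            raise ConfigError("'patients' entries must be mappings")
        _check_keys(entry, _PATIENT_KEYS, "patients.")
        try:
            patients.append(
                PatientProfile(
                    patient_id=int(entry["patient_id"]),
                    ward_id=int(entry.get("ward_id", ward_id)),
                    min_temp=float(entry["min_temp"]),
                    max_temp=float(entry["max_temp"]),
                    min_hr=float(entry["min_hr"]),
                    max_hr=float(entry["max_hr"]),
                )
            )
        except KeyError as exc:
            raise ConfigError(f"patient entry missing key {exc.args[0]!r}") from exc
    return tuple(patients)


def _parse_rates(raw: dict) -> dict[ArtifactCause, float]:
    if not isinstance(raw, dict):
        raise ConfigError("'artifact_rates' must be a mapping of cause to rate")
    rates = {cause: 0.0 for cause in ArtifactCause}
    for key, value in raw.items():
        try:
            cause = ArtifactCause(key)
        except ValueError as exc:
            raise ConfigError(f"unknown artifact cause in artifact_rates: {key!r}") from exc
        rates[cause] = float(value)
    return rates


def _build(data: dict) -> RunConfig:
    _check_keys(data, _TOP_KEYS, "")
    sim_kwargs: dict = {}
    ward_id = int(data.get("ward_id", 1))
    sim_kwargs["ward_id"] = ward_id
    if "patients" in data:
        sim_kwargs["patients"] = _parse_patients(data["patients"], ward_id)
    for key in ("temp_range", "hr_range"):
        if key in data:
            pair = data[key]
            if not isinstance(pair, (list, tuple)) or len(pair) != 2:
                raise ConfigError(f"{key!r} must be a [min, max] pair")
            cast = float if key == "temp_range" else int
            sim_kwargs[key] = (cast(pair[0]), cast(pair[1]))
    for key in ("reading_interval", "duration", "artifact_hold"):
        if key in data:
            sim_kwargs[key] = float(data[key])
    if "artifact_rates" in data:
        sim_kwargs["artifact_rates"] = _parse_rates(data["artifact_rates"])
    if "start_time" in data:
        raw_ts = data["start_time"]
        sim_kwargs["start_time"] = (
            raw_ts if isinstance(raw_ts, datetime) else datetime.fromisoformat(str(raw_ts))
        )
    if "seed" in data:
        sim_kwargs["seed"] = int(data["seed"])

    reasoner_kwargs: dict = {}
    raw_reasoner = data.get("reasoner", {})
    if not isinstance(raw_reasoner, dict):
        raise ConfigError("'reasoner' must be a mapping")
    _check_keys(raw_reasoner, _REASONER_KEYS, "reasoner.")
    for key, value in raw_reasoner.items():
        if key == "weights":
            if not isinstance(value, (list, tuple)) or len(value) != 4:
                raise ConfigError("reasoner.weights must be a list of four numbers")
            reasoner_kwargs[key] = tuple(float(w) for w in value)
        elif key == "bed_location":
            reasoner_kwargs[key] = str(value)
        else:
            reasoner_kwargs[key] = float(value)

    try:
        simulation = SimulationConfig(**sim_kwargs)
        reasoner = ReasonerParams(**reasoner_kwargs)
    except ConfigError:
        raise
    return RunConfig(
        simulation=simulation,
        reasoner=reasoner,
        window=float(data.get("window", 300.0)),
    )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    ``None`` or an empty file yields the full default configuration.
    """
    if path is None:
        return _build({})
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return _build(data)


def config_to_dict(config: RunConfig) -> dict:
    """The effective configuration as a plain, YAML-serialisable mapping."""
    sim = config.simulation
    reasoner = config.reasoner
    return {
        "ward_id": sim.ward_id,
        "patients": [
            {
                "patient_id": p.patient_id,
                "ward_id": p.ward_id,
                "min_temp": p.min_temp,
                "max_temp": p.max_temp,
                "min_hr": p.min_hr,
                "max_hr": p.max_hr,
            }
            for p in sim.patients
        ],
        "temp_range": list(sim.temp_range),
        "hr_range": list(sim.hr_range),
        "reading_interval": sim.reading_interval,
        "duration": sim.duration,
        "artifact_rates": {cause.value: rate for cause, rate in sim.artifact_rates.items()},
        "artifact_hold": sim.artifact_hold,
        "start_time": sim.start_time.isoformat(),
        "seed": sim.seed,
        "reasoner": {
            "weights": list(reasoner.weights),
            "fap_not_min": reasoner.fap_not_min,
            "battery_low_threshold": reasoner.battery_low_threshold,
            "battery_life": reasoner.battery_life,
            "skin_prep_max_age": reasoner.skin_prep_max_age,
            "electrode_max_age": reasoner.electrode_max_age,
            "mobility_window": reasoner.mobility_window,
            "repositioning_window": reasoner.repositioning_window,
            "bed_location": reasoner.bed_location,
        },
        "window": config.window,
    }


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective configuration so a run can be reproduced exactly."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False), encoding="utf-8"
    )


DEFAULT_START = DEFAULT_START_TIME  # re-export for convenience
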