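"""End-to-end run: simulate → detect → reason → notify → evaluate.

Also provides replay mode, which re-applies the labelling rule to a
previously recorded notification table without touching any other column.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig, config_to_dict, save_config
from .detection import AlarmCounter, detect_anomaly, mint_alarm
from .errors import ConfigError
from .evaluation import ConfusionSummary, ScoredAlarm, evaluate_labels, threshold_sweep
from .notifier import Notification, NotificationBatcher
from .records import (
    format_label,
    format_timestamp,
    notifications_to_frame,
    write_records,
)
from .reasoner import score_alarm
from .simulator import Vital, simulate_context, simulate_vitals

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """Everything a completed pipeline run produced."""

    config: RunConfig
    alarms: list[ScoredAlarm]
    notifications: list[Notification]
    summary: ConfusionSummary

    def records(self, vital: Vital) -> pd.DataFrame:
        notes = [n for n in self.notifications if n.vital is vital]
        return notifications_to_frame(notes)


def run_simulation(config: RunConfig) -> RunResult:
    """Execute one full seeded run of the pipeline in memory.

    Readings are processed in event-time order: due batches are flushed
    before each reading is screened, anomalous readings are scored and
    routed, and at the end every remaining batch is flushed at its
    scheduled time — so every minted alarm is delivered exactly once.
    """
    sim = config.simulation
    vitals = simulate_vitals(sim)
    contexts = simulate_context(sim, vitals)
    profiles = {p.patient_id: p for p in sim.patients}

    counter = AlarmCounter()
    batcher = NotificationBatcher(window=config.window)
    notifications: list[Notification] = []
    scored: list[ScoredAlarm] = []

    for reading in vitals:
        notifications.extend(batcher.flush_due(reading.timestamp))
        direction = detect_anomaly(reading, profiles[reading.patient_id])
        if direction is None:
            continue
        context = contexts[(reading.patient_id, reading.timestamp)]
        alarm = mint_alarm(reading, direction, context, counter, sim.ward_id)
        alarm, decision = score_alarm(alarm, config.reasoner)
        scored.append((alarm, decision))
        immediate = batcher.route_alarm(alarm, decision)
        if immediate is not None:
            notifications.append(immediate)
    notifications.extend(batcher.close())

    summary = evaluate_labels(scored)
    logger.info(
        "run complete: %d readings, %d alarms, %d notifications",
        len(vitals),
        len(scored),
        len(notifications),
    )
    return RunResult(
        config=config, alarms=scored, notifications=notifications, summary=summary
    )


def _event_log_lines(result: RunResult) -> list[str]:
    lines = []
    for alarm, decision in result.alarms:
        lines.append(
            json.dumps(
                {
                    "type": "alarm",
                    "alarm_id": alarm.alarm_id,
                    "ward_id": alarm.ward_id,
                    "patient_id": alarm.patient_id,
                    "vital": alarm.vital.value,
                    "sensor_value": alarm.sensor_value,
                    "timestamp": format_timestamp(alarm.alarm_timestamp),
                    "direction": alarm.direction.value,
                    "fai_vector": list(alarm.fai_vector.as_tuple()),
                    "fap": alarm.fap,
                    "fap_label": format_label(decision.label),
                    "truth_artifact_causes": sorted(
                        c.value for c in (alarm.context.truth_artifact_causes or ())
                    ),
                },
                sort_keys=True,
            )
        )
    for note in result.notifications:
        lines.append(
            json.dumps(
                {
                    "type": "notification",
                    "notification_id": note.notification_id,
                    "ward_id": note.ward_id,
                    "patient_id": note.patient_id,
                    "vital": note.vital.value,
                    "timestamp": format_timestamp(note.notification_timestamp),
                    "alarm_ids": [a.alarm_id for a, _ in note.alarms],
                },
                sort_keys=True,
            )
        )
    return lines


def _summary_frame(summary: ConfusionSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "true_positive": summary.true_positive,
                "false_positive": summary.false_positive,
                "true_negative": summary.true_negative,
                "false_negative": summary.false_negative,
                "precision": summary.precision,
                "recall": summary.recall,
                "specificity": summary.specificity,
            }
        ]
    )


def run_pipeline(
    config: RunConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run the pipeline and, if ``out_dir`` is given, write all artifacts.

    Outputs: one record table per vital (``temperature_records.csv``,
    ``heart_rate_records.csv``), the event log (``events.jsonl``), the
    evaluation summary and threshold sweep (``metrics.csv``,
    ``threshold_sweep.csv``), and the effective configuration with its seed
    (``effective_config.yaml``) for exact reproduction.
    """
    if seed is not None:
        config = dataclasses.replace(
            config,
            simulation=dataclasses.replace(config.simulation, seed=int(seed)),
        )
    result = run_simulation(config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(result.records(Vital.TEMPERATURE), out / "temperature_records.csv")
        write_records(result.records(Vital.HEART_RATE), out / "heart_rate_records.csv")
        (out / "events.jsonl").write_text(
            "".join(line + "\n" for line in _event_log_lines(result)), encoding="utf-8"
        )
        _summary_frame(result.summary).to_csv(out / "metrics.csv", index=False, lineterminator="\n")
        sweep = threshold_sweep(result.alarms, [0.0, 25.0, 50.0, 75.0, 100.0])
        sweep.to_csv(out / "threshold_sweep.csv", index=False, lineterminator="\n")
        save_config(config, out / "effective_config.yaml")
    return result


def replay_labels(table: pd.DataFrame, fap_not_min: float) -> pd.DataFrame:
    """Recompute the FAP_LABEL column of a record table from its FAP column.

    Every other column is left untouched.  Rows whose FAP falls outside
    [0, 100] are rejected with a logged reason.
    """
    if "FAP" not in table.columns:
        raise ConfigError("replay input must contain a FAP column")
    out = table.copy()
    faps = pd.to_numeric(out["FAP"], errors="coerce")
    bad = faps.isna() | (faps < 0) | (faps > 100)
    for idx in out.index[bad]:
        logger.warning("rejecting row %s: FAP %r outside [0, 100]", idx, out.at[idx, "FAP"])
    out = out.loc[~bad].copy()
    kept = faps.loc[~bad]
    out["FAP_LABEL"] = [
        f"{fap:.1f}" if fap >= fap_not_min else "UNDEFINED" for fap in kept
    ]
    return out


def effective_config_dict(config: RunConfig) -> dict:
    return config_to_dict(config)
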