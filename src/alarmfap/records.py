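"""Notification record tables: the output layout, CSV I/O, and examples.

One record binds one alarm to the notification that delivered it:

    NID, WID, PID, AID, sensor_value, alarm_timestamp, FAP,
    notification_timestamp, FAP_LABEL

Records sharing a NID belong to one batched notification and share its
notification timestamp.  FAP and FAP_LABEL are printed with one decimal
place; an unlabelled record carries the literal string ``UNDEFINED``.
Timestamps are ISO-8601 with millisecond precision.

The module also bundles a small worked-example dataset: the default
four-patient threshold table and ten temperature plus ten heart-rate
notification records from a reference run of the system, used by the
documentation, the replay tests, and ``alarmfap fixtures``.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import pandas as pd

from .notifier import Notification
from .reasoner import UNDEFINED
from .simulator import Vital

RESULT_COLUMNS = [
    "NID",
    "WID",
    "PID",
    "AID",
    "sensor_value",
    "alarm_timestamp",
    "FAP",
    "notification_timestamp",
    "FAP_LABEL",
]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


def format_timestamp(ts: datetime) -> str:
    """ISO-8601 with exactly millisecond precision."""
    return ts.strftime(_TS_FORMAT)[:-3]


def parse_timestamp(text: str) -> datetime:
    return datetime.fromisoformat(text)


def format_fap(fap: float) -> str:
    return f"{fap:.1f}"


def format_label(label: float | None) -> str:
    return UNDEFINED if label is None else format_fap(label)


def notifications_to_frame(notifications: list[Notification]) -> pd.DataFrame:
    """Flatten notifications into the one-row-per-alarm record table.

    Rows are ordered by NID, then alarm timestamp, matching how batched
    notifications are reported.
    """
    rows = []
    for note in sorted(notifications, key=lambda n: n.notification_id):
        for alarm, decision in note.alarms:
            rows.append(
                {
                    "NID": note.notification_id,
                    "WID": note.ward_id,
                    "PID": note.patient_id,
                    "AID": alarm.alarm_id,
                    "sensor_value": alarm.sensor_value,
                    "alarm_timestamp": format_timestamp(alarm.alarm_timestamp),
                    "FAP": format_fap(decision.fap),
                    "notification_timestamp": format_timestamp(
                        note.notification_timestamp
                    ),
                    "FAP_LABEL": format_label(decision.label),
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_records(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a record table as UTF-8 CSV with a header row."""
    frame.to_csv(path, index=False, lineterminator="\n")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a record table, preserving FAP/label formatting and timestamps.

    FAP and FAP_LABEL are kept as strings (``"75.0"`` / ``"UNDEFINED"``) so
    a write → read → write round-trip is byte-identical.
    """
    return pd.read_csv(
        path,
        dtype={
            "NID": int,
            "WID": int,
            "PID": int,
            "AID": int,
            "sensor_value": float,
            "alarm_timestamp": str,
            "FAP": str,
            "notification_timestamp": str,
            "FAP_LABEL": str,
        },
    )


def _example_frame(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=RESULT_COLUMNS).astype(
        {"NID": int, "WID": int, "PID": int, "AID": int, "sensor_value": float}
    )


# Worked example: first ten temperature-alarm notification records of a
# reference run (ward 1, four patients, FAP_NOT_MIN 75%, 300 s batches).
EXAMPLE_TEMPERATURE_ROWS: list[tuple] = [
    (1, 1, 1, 1, 35.0, "2019-07-02T21:51:06.291", "50.0", "2019-07-02T21:51:06.334", "UNDEFINED"),
    (2, 1, 4, 2, 42.0, "2019-07-02T21:51:08.328", "25.0", "2019-07-02T21:51:08.328", "UNDEFINED"),
    (3, 1, 3, 4, 41.0, "2019-07-02T21:51:12.457", "50.0", "2019-07-02T21:51:12.457", "UNDEFINED"),
    (4, 1, 2, 9, 41.0, "2019-07-02T21:51:43.223", "75.0", "2019-07-02T21:51:43.223", "75.0"),
    (5, 1, 1, 12, 42.0, "2019-07-02T21:52:03.697", "50.0", "2019-07-02T21:56:06.334", "UNDEFINED"),
    (5, 1, 1, 15, 42.0, "2019-07-02T21:52:20.053", "100.0", "2019-07-02T21:56:06.334", "100.0"),
    (5, 1, 1, 16, 41.0, "2019-07-02T21:52:24.135", "75.0", "2019-07-02T21:56:06.334", "75.0"),
    (5, 1, 1, 17, 35.0, "2019-07-02T21:52:32.309", "25.0", "2019-07-02T21:56:06.334", "UNDEFINED"),
    (5, 1, 1, 18, 42.0, "2019-07-02T21:52:42.594", "50.0", "2019-07-02T21:56:06.334", "UNDEFINED"),
    (5, 1, 1, 20, 41.0, "2019-07-02T21:52:50.774", "50.0", "2019-07-02T21:56:06.334", "UNDEFINED"),
]

# Worked example: first ten heart-rate notification records of the same run.
EXAMPLE_HEART_RATE_ROWS: list[tuple] = [
    (1, 1, 2, 1, 108.0, "2019-07-02T21:51:09.375", "75.0", "2019-07-02T21:51:09.390", "75.0"),
    (2, 1, 1, 2, 145.0, "2019-07-02T21:51:11.432", "25.0", "2019-07-02T21:51:11.432", "UNDEFINED"),
    (3, 1, 4, 6, 123.0, "2019-07-02T21:51:21.721", "50.0", "2019-07-02T21:51:21.722", "UNDEFINED"),
    (4, 1, 3, 8, 116.0, "2019-07-02T21:51:25.827", "50.0", "2019-07-02T21:51:25.827", "UNDEFINED"),
    (5, 1, 2, 3, 156.0, "2019-07-02T21:51:15.539", "0.0", "2019-07-02T21:56:09.397", "UNDEFINED"),
    (5, 1, 2, 5, 159.0, "2019-07-02T21:51:19.667", "50.0", "2019-07-02T21:56:09.397", "UNDEFINED"),
    (5, 1, 2, 7, 44.0, "2019-07-02T21:51:23.776", "75.0", "2019-07-02T21:56:09.397", "75.0"),
    (5, 1, 2, 9, 164.0, "2019-07-02T21:51:27.874", "50.0", "2019-07-02T21:56:09.397", "UNDEFINED"),
    (5, 1, 2, 16, 184.0, "2019-07-02T21:51:44.254", "25.0", "2019-07-02T21:56:09.397", "UNDEFINED"),
    (5, 1, 2, 23, 51.0, "2019-07-02T21:52:00.641", "0.0", "2019-07-02T21:56:09.397", "UNDEFINED"),
]


def example_records(vital: Vital) -> pd.DataFrame:
    """The bundled worked-example record table for one vital type."""
    rows = (
        EXAMPLE_TEMPERATURE_ROWS
        if vital is Vital.TEMPERATURE
        else EXAMPLE_HEART_RATE_ROWS
    )
    return _example_frame(rows)


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the bundled threshold table and example record tables as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .simulator import DEFAULT_PATIENTS

    thresholds = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "min_temp": p.min_temp,
                "max_temp": p.max_temp,
                "min_hr": p.min_hr,
                "max_hr": p.max_hr,
            }
            for p in DEFAULT_PATIENTS
        ]
    )
    paths = []
    for name, frame in [
        ("patient_thresholds.csv", thresholds),
        ("example_temperature_records.csv", example_records(Vital.TEMPERATURE)),
        ("example_heart_rate_records.csv", example_records(Vital.HEART_RATE)),
    ]:
        path = out / name
        frame.to_csv(path, index=False, lineterminator="\n")
        paths.append(path)
    return paths
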