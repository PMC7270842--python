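"""Notification assembly: immediate first alarm, delayed batch thereafter.

The first alarm of a (patient, vital) stream is sent to caregivers
immediately as its own notification; at the same moment a batch opens that
collects every subsequent alarm for that patient and vital.  The batch is
flushed exactly one delay window (default 300 s) after it opened, stamped
with the scheduled flush time rather than the wall clock, and the next
alarm after a flush starts a new immediate notification.

No alarm is ever dropped: whatever its FAP — including 100% — every alarm
appears in exactly one flushed notification.  Labelling only annotates;
delivery is unconditional.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .detection import AlarmEvent
from .errors import TimeReversalError
from .reasoner import LabelDecision
from .simulator import Vital


class NotificationState(str, enum.Enum):
    OPEN = "OPEN"
    FLUSHED = "FLUSHED"


@dataclass
class Notification:
    """A message to caregivers carrying one alarm or a batched group.

    All alarms in one notification share patient and vital; batched alarms
    are ordered by alarm timestamp.
    """

    notification_id: int
    ward_id: int
    patient_id: int
    vital: Vital
    alarms: list[tuple[AlarmEvent, LabelDecision]]
    notification_timestamp: datetime
    state: NotificationState = NotificationState.FLUSHED


@dataclass
class _OpenBatch:
    opened_at: datetime
    ward_id: int
    patient_id: int
    vital: Vital
    alarms: list[tuple[AlarmEvent, LabelDecision]] = field(default_factory=list)


class NotificationBatcher:
    """Stateful router implementing the immediate-first / delayed-batch policy.

    Notification IDs are sequential per (ward, vital) stream and assigned in
    emission order — immediate notifications when routed, batches when
    flushed — so a batch opened early still receives a later NID than the
    single-alarm notifications emitted while it was filling.
    """

    def __init__(self, window: float = 300.0) -> None:
        if window <= 0:
            raise ValueError("window must be positive")
        self.window = timedelta(seconds=window)
        self._open: dict[tuple[int, int, Vital], _OpenBatch] = {}
        self._next_nid: dict[tuple[int, Vital], int] = {}
        self._clock: datetime | None = None

    def _advance(self, now: datetime) -> None:
        if self._clock is not None and now < self._clock:
            raise TimeReversalError(
                f"event clock moved backwards: {now} < {self._clock}"
            )
        self._clock = now

    def _take_nid(self, ward_id: int, vital: Vital) -> int:
        key = (ward_id, vital)
        nid = self._next_nid.get(key, 1)
        self._next_nid[key] = nid + 1
        return nid

    def route_alarm(
        self,
        alarm: AlarmEvent,
        decision: LabelDecision,
        now: datetime | None = None,
    ) -> Notification | None:
        """Route one alarm; returns an immediate notification when one is sent.

        ``now`` is the processing instant (defaults to the alarm timestamp).
        If no batch is open for the alarm's (patient, vital), the alarm goes
        out at once and a batch opens, due to flush one window later;
        otherwise the alarm joins the open batch and nothing is emitted yet.
        """
        now = now if now is not None else alarm.alarm_timestamp
        self._advance(now)
        key = (alarm.ward_id, alarm.patient_id, alarm.vital)
        batch = self._open.get(key)
        if batch is not None:
            batch.alarms.append((alarm, decision))
            return None
        self._open[key] = _OpenBatch(
            opened_at=now,
            ward_id=alarm.ward_id,
            patient_id=alarm.patient_id,
            vital=alarm.vital,
        )
        return Notification(
            notification_id=self._take_nid(alarm.ward_id, alarm.vital),
            ward_id=alarm.ward_id,
            patient_id=alarm.patient_id,
            vital=alarm.vital,
            alarms=[(alarm, decision)],
            notification_timestamp=now,
        )

    def flush_due(self, now: datetime) -> list[Notification]:
        """Flush every open batch whose window has elapsed by ``now``.

        A flushed batch is stamped with its scheduled time (open timestamp
        plus the window) to the millisecond, not with ``now``.  Batches that
        collected no alarms close silently.
        """
        self._advance(now)
        due = [
            (key, batch)
            for key, batch in self._open.items()
            if batch.opened_at + self.window <= now
        ]
        due.sort(key=lambda kv: (kv[1].opened_at, kv[1].patient_id, kv[1].vital.value))
        flushed: list[Notification] = []
        for key, batch in due:
            del self._open[key]
            if not batch.alarms:
                continue
            batch.alarms.sort(key=lambda ad: ad[0].alarm_timestamp)
            flushed.append(
                Notification(
                    notification_id=self._take_nid(batch.ward_id, batch.vital),
                    ward_id=batch.ward_id,
                    patient_id=batch.patient_id,
                    vital=batch.vital,
                    alarms=batch.alarms,
                    notification_timestamp=batch.opened_at + self.window,
                )
            )
        return flushed

    def close(self) -> list[Notification]:
        """Flush all remaining batches at their scheduled times (end of run)."""
        if not self._open:
            return []
        horizon = max(b.opened_at for b in self._open.values()) + self.window
        return self.flush_due(horizon)
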