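"""Notifier: immediate-first policy, exact flush arithmetic, conservation."""

from datetime import datetime, timedelta

import pytest

from alarmfap import (
    AlarmCounter,
    Direction,
    LabelDecision,
    NotificationBatcher,
    TimeReversalError,
    Vital,
    mint_alarm,
    run_simulation,
)
from conftest import make_context, make_reading

T0 = datetime(2019, 7, 2, 21, 51, 6, 334000)


def alarm_at(counter, seconds=0.0, patient_id=1, vital=Vital.TEMPERATURE, value=34.0):
    at = T0 + timedelta(seconds=seconds)
    reading = make_reading(patient_id=patient_id, vital=vital, value=value, at=at)
    return mint_alarm(reading, Direction.LOW, make_context(at=at), counter, ward_id=1)


def decision(fap=50.0, label=None):
    return LabelDecision(fap=fap, label=label)


class TestRouting:
    def test_first_alarm_is_notified_immediately(self):
        batcher = NotificationBatcher(window=300.0)
        note = batcher.route_alarm(alarm_at(AlarmCounter()), decision())
        assert note is not None
        assert note.notification_id == 1
        assert note.notification_timestamp == T0
        assert len(note.alarms) == 1

    def test_subsequent_alarms_join_the_open_batch(self):
        batcher = NotificationBatcher(window=300.0)
        counter = AlarmCounter()
        assert batcher.route_alarm(alarm_at(counter, 0), decision()) is not None
        assert batcher.route_alarm(alarm_at(counter, 10), decision()) is None
        assert batcher.route_alarm(alarm_at(counter, 20), decision()) is None

    def test_batches_are_per_patient(self):
        batcher = NotificationBatcher(window=300.0)
        counter = AlarmCounter()
        n1 = batcher.route_alarm(alarm_at(counter, 0, patient_id=1), decision())
        n2 = batcher.route_alarm(alarm_at(counter, 1, patient_id=2), decision())
        assert n1 is not None and n2 is not None
        assert {n1.notification_id, n2.notification_id} == {1, 2}

    def test_batches_are_per_vital(self):
        batcher = NotificationBatcher(window=300.0)
        counter = AlarmCounter()
        t = batcher.route_alarm(alarm_at(counter, 0, vital=Vital.TEMPERATURE), decision())
        h = batcher.route_alarm(
            alarm_at(counter, 1, vital=Vital.HEART_RATE, value=30.0), decision()
        )
        # NID counters are independent per vital stream, so both start at 1.
        assert t.notification_id == 1 and h.notification_id == 1


class TestFlushing:
    def test_flush_stamp_is_open_time_plus_window_exactly(self):
        batcher = NotificationBatcher(window=300.0)
        counter = AlarmCounter()
        batcher.route_alarm(alarm_at(counter, 0), decision())
        batcher.route_alarm(alarm_at(counter, 57.363), decision())
        flushed = batcher.flush_due(T0 + timedelta(seconds=301))
        assert len(flushed) == 1
        assert flushed[0].notification_timestamp == T0 + timedelta(seconds=300)

    def test_batched_alarms_share_nid_and_timestamp_in_time_order(self):
        batcher = NotificationBatcher(window=300.0)
        counter = AlarmCounter()
        batcher.route_alarm(alarm_at(counter, 0), decision())
        offsets = [57.363, 73.719, 77.801, 86.0, 96.3, 104.4]
        for s in offsets:
            batcher.route_alarm(alarm_at(counter, s), decision())
        (batch,) = batcher.flush_due(T0 + timedelta(seconds=400))
        assert batch.notification_id == 2
        stamps = [a.alarm_timestamp for a, _ in batch.alarms]
        assert stamps == sorted(stamps) and len(batch.alarms) == len(offsets)

    def test_window_not_elapsed_means_no_flush(self):
        batcher = NotificationBatcher(window=300.0)
        batcher.route_alarm(alarm_at(AlarmCounter()), decision())
        assert batcher.flush_due(T0 + timedelta(seconds=299.999)) == []

    def test_empty_batch_flushes_nothing(self):
        batcher = NotificationBatcher(window=300.0)
        batcher.route_alarm(alarm_at(AlarmCounter()), decision())
        # the opening alarm went out immediately; no further alarms arrived
        assert batcher.flush_due(T0 + timedelta(seconds=600)) == []

    def test_alarm_after_flush_starts_a_new_immediate_notification(self):
        batcher = NotificationBatcher(window=300.0)
        counter = AlarmCounter()
        batcher.route_alarm(alarm_at(counter, 0), decision())
        batcher.route_alarm(alarm_at(counter, 10), decision())
        batcher.flush_due(T0 + timedelta(seconds=301))
        note = batcher.route_alarm(alarm_at(counter, 302), decision())
        assert note is not None and note.notification_id == 3

    def test_time_moving_backwards_is_a_hard_error(self):
        batcher = NotificationBatcher(window=300.0)
        batcher.flush_due(T0 + timedelta(seconds=10))
        with pytest.raises(TimeReversalError):
            batcher.flush_due(T0)

    def test_close_flushes_open_batches_at_their_scheduled_times(self):
        batcher = NotificationBatcher(window=300.0)
        counter = AlarmCounter()
        batcher.route_alarm(alarm_at(counter, 0), decision())
        batcher.route_alarm(alarm_at(counter, 5), decision())
        (batch,) = batcher.close()
        assert batch.notification_timestamp == T0 + timedelta(seconds=300)


class TestConservation:
    def test_every_alarm_is_delivered_exactly_once_in_a_full_run(self, small_run_config):
        result = run_simulation(small_run_config)
        minted = sorted((a.vital, a.alarm_id) for a, _ in result.alarms)
        delivered = sorted(
            (a.vital, a.alarm_id) for n in result.notifications for a, _ in n.alarms
        )
        assert minted == delivered  # nothing lost, nothing duplicated

    def test_high_fap_alarms_are_still_delivered(self, small_run_config):
        result = run_simulation(small_run_config)
        threshold = small_run_config.reasoner.fap_not_min
        labelled = [a.alarm_id for a, d in result.alarms if d.labelled]
        delivered = {a.alarm_id for n in result.notifications for a, _ in n.alarms}
        assert set(labelled) <= delivered
        for _, d in result.alarms:
            assert d.labelled == (d.fap >= threshold)

    def test_nid_sequence_contiguous_per_vital_stream(self, small_run_config):
        result = run_simulation(small_run_config)
        for vital in Vital:
            nids = sorted(
                n.notification_id for n in result.notifications if n.vital is vital
            )
            assert nids == list(range(1, len(nids) + 1))
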