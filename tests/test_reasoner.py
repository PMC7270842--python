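"""Reasoner: FAI activation rules, FAP aggregation, and the label decision."""

import dataclasses
import itertools
from datetime import timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alarmfap import (
    AlarmContext,
    ConfigError,
    FAIVector,
    ReasonerParams,
    compute_fap,
    decide_label,
    fai_battery,
    fai_mobility,
    fai_placement,
    fai_repositioning,
)
from conftest import NOW, make_context


def context_with(**overrides) -> AlarmContext:
    return dataclasses.replace(make_context(), **overrides)


class TestBatteryIndicator:
    def test_low_charge_activates(self, params):
        ctx = context_with(level_of_battery=10.0)
        assert fai_battery(ctx, NOW, params) == 1

    def test_fresh_full_battery_is_inactive(self, params):
        assert fai_battery(make_context(), NOW, params) == 0

    def test_overdue_change_activates_even_at_full_charge(self, params):
        ctx = context_with(last_time_battery_changed=NOW - timedelta(hours=30))
        assert fai_battery(ctx, NOW, params) == 1

    def test_missing_inputs_fail_safe_to_inactive(self, params, caplog):
        ctx = context_with(level_of_battery=None, last_time_battery_changed=None)
        with caplog.at_level("WARNING"):
            assert fai_battery(ctx, NOW, params) == 0
        assert "level_of_battery" in caplog.text


class TestPlacementIndicator:
    def test_recent_prep_and_electrodes_inactive(self, params):
        assert fai_placement(make_context(), NOW, params) == 0

    def test_stale_electrodes_activate(self, params):
        ctx = context_with(last_time_electrodes_changed=NOW - timedelta(hours=48))
        assert fai_placement(ctx, NOW, params) == 1

    def test_stale_skin_prep_alone_activates(self, params):
        ctx = context_with(
            last_time_skin_preparation=NOW - timedelta(hours=25),
            last_time_electrodes_changed=NOW - timedelta(hours=1),
        )
        assert fai_placement(ctx, NOW, params) == 1


class TestMobilityIndicator:
    def test_patient_in_bed_with_stable_log_inactive(self, params):
        assert fai_mobility(make_context(), NOW, params) == 0

    def test_away_from_bed_activates(self, params):
        ctx = context_with(current_patient_localization="corridor")
        assert fai_mobility(ctx, NOW, params) == 1

    def test_recent_return_to_bed_activates(self, params):
        ctx = context_with(
            current_patient_localization="bed",
            log_last_patient_localization=((NOW - timedelta(seconds=30), "corridor"),),
        )
        assert fai_mobility(ctx, NOW, params) == 1

    def test_old_movement_outside_window_ignored(self, params):
        ctx = context_with(
            log_last_patient_localization=((NOW - timedelta(minutes=10), "corridor"),),
        )
        assert fai_mobility(ctx, NOW, params) == 0

    def test_empty_log_uses_only_current_location(self, params):
        ctx = context_with(log_last_patient_localization=())
        assert fai_mobility(ctx, NOW, params) == 0


class TestRepositioningIndicator:
    def test_stable_position_inactive(self, params):
        assert fai_repositioning(make_context(), NOW, params) == 0

    def test_recent_position_change_activates(self, params):
        ctx = context_with(
            log_last_patient_positions_in_bed=(
                (NOW - timedelta(seconds=30), "supine"),
                (NOW - timedelta(seconds=10), "lateral"),
            ),
        )
        assert fai_repositioning(ctx, NOW, params) == 1

    def test_change_outside_window_inactive(self, params):
        ctx = context_with(
            log_last_patient_positions_in_bed=(
                (NOW - timedelta(minutes=10), "lateral"),
                (NOW - timedelta(seconds=5), "supine"),
            ),
        )
        assert fai_repositioning(ctx, NOW, params) == 0

    def test_empty_log_inactive(self, params):
        ctx = context_with(log_last_patient_positions_in_bed=())
        assert fai_repositioning(ctx, NOW, params) == 0


class TestFapAggregation:
    def test_equal_weights_match_quarter_per_indicator_over_all_16_vectors(self, params):
        for bits in itertools.product((0, 1), repeat=4):
            vector = FAIVector(*bits)
            assert compute_fap(vector, params) == pytest.approx(25.0 * sum(bits))

    def test_default_fap_levels_are_multiples_of_25(self, params):
        levels = {
            compute_fap(FAIVector(*bits), params)
            for bits in itertools.product((0, 1), repeat=4)
        }
        assert levels == {0.0, 25.0, 50.0, 75.0, 100.0}

    @settings(deadline=None, derandomize=True)
    @given(
        bits=st.tuples(*[st.integers(0, 1)] * 4),
        raw=st.tuples(*[st.floats(0.01, 1.0)] * 4),
        flip=st.integers(0, 3),
    )
    def test_activating_one_more_indicator_never_decreases_fap(self, bits, raw, flip):
        total = sum(raw)
        weights = tuple(w / total for w in raw)
        params = ReasonerParams(weights=weights)
        lower = list(bits)
        lower[flip] = 0
        higher = list(lower)
        higher[flip] = 1
        assert compute_fap(FAIVector(*higher), params) >= compute_fap(
            FAIVector(*lower), params
        )

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            ReasonerParams(weights=(0.5, 0.5, 0.5, 0.5))

    def test_indicator_values_outside_binary_rejected(self):
        with pytest.raises(ValueError):
            FAIVector(battery=2)


class TestLabelDecision:
    @pytest.mark.parametrize(
        "fap, expected_label",
        [
            (0.0, None),
            (50.0, None),
            (74.9, None),
            (75.0, 75.0),  # at threshold: labelled ("higher than or equal to")
            (100.0, 100.0),
        ],
    )
    def test_threshold_rule(self, params, fap, expected_label):
        decision = decide_label(fap, params)
        assert decision.fap == fap
        assert decision.label == expected_label

    def test_defined_label_always_equals_fap(self, params):
        for fap in (75.0, 80.0, 100.0):
            decision = decide_label(fap, params)
            assert decision.labelled and decision.label == decision.fap

    def test_custom_threshold_is_honoured(self):
        params = ReasonerParams(fap_not_min=50.0)
        assert decide_label(50.0, params).labelled
        assert not decide_label(49.9, params).labelled

    def test_fap_outside_percent_scale_rejected(self, params):
        with pytest.raises(ValueError):
            decide_label(101.0, params)
        with pytest.raises(ValueError):
            decide_label(-1.0, params)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigError):
            ReasonerParams(fap_not_min=120.0)
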