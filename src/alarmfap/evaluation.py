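"""Scoring labelling decisions against simulator ground truth.

An alarm's truth is "artifact" (false alarm) iff at least one artifact
cause was active at its timestamp; the predicted positive is an alarm that
received a FAP_LABEL.  Errors therefore read as: false positive = a genuine
alarm flagged as probably false; false negative = an artifact alarm that
went out unflagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detection import AlarmEvent
from .errors import MissingGroundTruthError
from .reasoner import LabelDecision, ReasonerParams, decide_label


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and derived rates for a set of labelled alarms.

    Positive means labelled probable-false-alarm.  Ratios with a zero
    denominator are ``None`` (absent), never silently 0.
    """

    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int

    @property
    def total(self) -> int:
        return (
            self.true_positive
            + self.false_positive
            + self.true_negative
            + self.false_negative
        )

    @property
    def precision(self) -> float | None:
        denom = self.true_positive + self.false_positive
        return self.true_positive / denom if denom else None

    @property
    def recall(self) -> float | None:
        denom = self.true_positive + self.false_negative
        return self.true_positive / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.true_negative + self.false_positive
        return self.true_negative / denom if denom else None


ScoredAlarm = tuple[AlarmEvent, LabelDecision]


def _truth_is_artifact(alarm: AlarmEvent) -> bool:
    causes = alarm.context.truth_artifact_causes
    if causes is None:
        raise MissingGroundTruthError(
            f"alarm {alarm.alarm_id} carries no ground-truth artifact causes; "
            "evaluation is only valid on simulated streams"
        )
    return bool(causes)


def evaluate_labels(alarms: list[ScoredAlarm]) -> ConfusionSummary:
    """Tally label decisions against the simulator's injected causes."""
    tp = fp = tn = fn = 0
    for alarm, decision in alarms:
        artifact = _truth_is_artifact(alarm)
        positive = decision.labelled
        if positive and artifact:
            tp += 1
        elif positive and not artifact:
            fp += 1
        elif not positive and artifact:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp, fp, tn, fn)


def threshold_sweep(
    alarms: list[ScoredAlarm],
    thresholds: list[float],
    params: ReasonerParams | None = None,
) -> pd.DataFrame:
    """Re-apply the labelling rule at each threshold and tally the outcomes.

    The predicted-positive count is non-increasing in the threshold.
    Thresholds above 100 are allowed for sweeps (nothing is ever labelled
    there); each row reports the confusion counts and rates at one
    threshold.
    """
    params = params or ReasonerParams()
    rows = []
    for threshold in thresholds:
        relabelled = []
        for alarm, decision in alarms:
            effective = min(max(float(threshold), 0.0), 100.0)
            label = decision.fap if decision.fap >= effective and threshold <= 100 else None
            relabelled.append((alarm, LabelDecision(fap=decision.fap, label=label)))
        summary = evaluate_labels(relabelled)
        rows.append(
            {
                "threshold": float(threshold),
                "predicted_positive": summary.true_positive + summary.false_positive,
                "true_positive": summary.true_positive,
                "false_positive": summary.false_positive,
                "true_negative": summary.true_negative,
                "false_negative": summary.false_negative,
                "precision": summary.precision,
                "recall": summary.recall,
                "specificity": summary.specificity,
            }
        )
    return pd.DataFrame(rows)
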