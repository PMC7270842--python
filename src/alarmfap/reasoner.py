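"""False-alarm probability (FAP) reasoner.

Four binary false-alarm indicators (FAIs) are computed from an alarm's
context snapshot:

* **battery** — sensor battery low or overdue for a change;
* **placement** — skin preparation or electrode change overdue, so the
  sensor may no longer sit properly on the skin;
* **mobility** — the patient has left, or just returned to, the bed;
* **repositioning** — the patient recently changed position in bed.

The FAP is a weighted sum of the indicators on a percent scale,
``FAP = 100 * sum(w_i * fai_i)``, with equal weights (0.25 each) by
default, so the default FAP levels are {0, 25, 50, 75, 100}.  An alarm's
notification carries a FAP_LABEL equal to the FAP when the FAP is at or
above the configurable threshold ``fap_not_min`` (default 75%); below the
threshold the label is the sentinel UNDEFINED.  Labelling never suppresses
the alarm itself.

A missing context input makes its indicator contribute 0 (with a logged
warning): the fail-safe direction is to *not* flag an alarm as probably
false.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from datetime import datetime
from typing import TYPE_CHECKING

from .errors import ConfigError
from .simulator import AlarmContext

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .detection import AlarmEvent

logger = logging.getLogger(__name__)

#: Sentinel rendered for a notification whose FAP fell below the threshold.
UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class FAIVector:
    """The four binary false-alarm indicators of one alarm."""

    battery: int = 0
    placement: int = 0
    mobility: int = 0
    repositioning: int = 0

    def __post_init__(self) -> None:
        for name in ("battery", "placement", "mobility", "repositioning"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"indicator {name} must be 0 or 1")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.battery, self.placement, self.mobility, self.repositioning)

    @property
    def active_count(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class ReasonerParams:
    """Tunable parameters of the FAI rules and the labelling decision.

    Durations are in seconds.  ``weights`` follow the indicator order of
    :class:`FAIVector` and must sum to 1.
    """

    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    fap_not_min: float = 75.0
    battery_low_threshold: float = 20.0
    battery_life: float = 24 * 3600.0
    skin_prep_max_age: float = 24 * 3600.0
    electrode_max_age: float = 24 * 3600.0
    mobility_window: float = 60.0
    repositioning_window: float = 60.0
    bed_location: str = "bed"

    def __post_init__(self) -> None:
        if len(self.weights) != 4 or any(w < 0 for w in self.weights):
            raise ConfigError("weights must be four non-negative numbers")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ConfigError(f"weights must sum to 1, got {sum(self.weights)}")
        if not 0.0 <= self.fap_not_min <= 100.0:
            raise ConfigError("fap_not_min must lie in [0, 100]")


@dataclass(frozen=True)
class LabelDecision:
    """Outcome of the labelling rule for one alarm.

    ``label`` is the FAP itself when the FAP met the threshold, else
    ``None`` (rendered as the UNDEFINED sentinel in output tables).
    """

    fap: float
    label: float | None

    @property
    def labelled(self) -> bool:
        return self.label is not None


def _age(at: datetime, then: datetime) -> float:
    return (at - then).total_seconds()


def fai_battery(context: AlarmContext, at: datetime, params: ReasonerParams) -> int:
    """1 iff the battery level is below threshold or the battery is overdue."""
    active = False
    if context.level_of_battery is None:
        logger.warning("missing level_of_battery; battery indicator forced inactive")
    else:
        active = context.level_of_battery < params.battery_low_threshold
    if context.last_time_battery_changed is None:
        logger.warning("missing last_time_battery_changed; condition skipped")
    else:
        active = active or _age(at, context.last_time_battery_changed) > params.battery_life
    return int(active)


def fai_placement(context: AlarmContext, at: datetime, params: ReasonerParams) -> int:
    """1 iff skin preparation or the last electrode change is overdue."""
    active = False
    if context.last_time_skin_preparation is None:
        logger.warning("missing last_time_skin_preparation; condition skipped")
    else:
        active = _age(at, context.last_time_skin_preparation) > params.skin_prep_max_age
    if context.last_time_electrodes_changed is None:
        logger.warning("missing last_time_electrodes_changed; condition skipped")
    else:
        active = active or _age(at, context.last_time_electrodes_changed) > params.electrode_max_age
    return int(active)


def fai_mobility(context: AlarmContext, at: datetime, params: ReasonerParams) -> int:
    """1 iff the patient is away from bed or moved within the mobility window.

    Away-from-bed is the current localization differing from the assigned
    bed location; recent movement is the most recent localization-log entry
    inside the window differing from the current localization.
    """
    current = context.current_patient_localization
    if current is None:
        logger.warning("missing current_patient_localization; mobility indicator forced inactive")
        return 0
    if current != params.bed_location:
        return 1
    recent = [
        label
        for ts, label in context.log_last_patient_localization
        if 0.0 <= _age(at, ts) <= params.mobility_window
    ]
    return int(bool(recent) and recent[-1] != current)


def fai_repositioning(context: AlarmContext, at: datetime, params: ReasonerParams) -> int:
    """1 iff a bed-position change is visible inside the repositioning window.

    A change is either a log entry in the window differing from the current
    position, or two successive in-window log entries that differ.
    """
    current = context.current_patient_position_in_bed
    in_window = [
        label
        for ts, label in context.log_last_patient_positions_in_bed
        if 0.0 <= _age(at, ts) <= params.repositioning_window
    ]
    if not in_window:
        return 0
    if current is not None and any(label != current for label in in_window):
        return 1
    return int(len(in_window) >= 2 and in_window[-1] != in_window[-2])


def evaluate_fais(context: AlarmContext, at: datetime, params: ReasonerParams) -> FAIVector:
    """Compute all four indicators for one context snapshot."""
    return FAIVector(
        battery=fai_battery(context, at, params),
        placement=fai_placement(context, at, params),
        mobility=fai_mobility(context, at, params),
        repositioning=fai_repositioning(context, at, params),
    )


def compute_fap(fais: FAIVector, params: ReasonerParams) -> float:
    """Aggregate the indicators into a FAP on the percent scale."""
    return 100.0 * sum(w * f for w, f in zip(params.weights, fais.as_tuple()))


def decide_label(fap: float, params: ReasonerParams) -> LabelDecision:
    """Attach the FAP as the label iff it is at or above ``fap_not_min``.

    The decision only controls whether the label rides along with the
    notification; the alarm is always delivered.
    """
    if not 0.0 <= fap <= 100.0:
        raise ValueError(f"fap must lie in [0, 100], got {fap}")
    return LabelDecision(fap=fap, label=fap if fap >= params.fap_not_min else None)


def score_alarm(alarm: "AlarmEvent", params: ReasonerParams) -> tuple["AlarmEvent", LabelDecision]:
    """Fill an alarm's FAI vector and FAP and return its label decision."""
    fais = evaluate_fais(alarm.context, alarm.alarm_timestamp, params)
    fap = compute_fap(fais, params)
    return replace(alarm, fai_vector=fais, fap=fap), decide_label(fap, params)
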