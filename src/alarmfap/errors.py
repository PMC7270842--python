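"""Package-level exception types."""


class AlarmFapError(Exception):
    """Base class for all package errors."""


class ConfigError(AlarmFapError):
    """A configuration value violates its contract."""


class TimeReversalError(AlarmFapError):
    """The event clock moved backwards; the stream is not time-ordered."""


class MissingGroundTruthError(AlarmFapError):
    """Evaluation requested on alarms that carry no simulator ground truth."""
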