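"""Exception hierarchy for the QA pipeline.

Every stage raises a subclass of :class:`ProtonQAError` so that the
orchestrator can attribute failures to a stage without string matching.
"""


class ProtonQAError(Exception):
    """Base class for all package errors."""


class PlanFormatError(ProtonQAError):
    """A DICOM RT Ion Plan is missing required spot-map attributes."""


class PlanArithmeticError(ProtonQAError):
    """Meterset conversion is impossible (e.g. zero final cumulative weight)."""


class LogFormatError(ProtonQAError):
    """A delivery log file is not a recognised PQA1 file."""


class LogCorruptionError(ProtonQAError):
    """A delivery log file is truncated or internally inconsistent."""

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class SynchronizationError(ProtonQAError):
    """Plan and delivery log cannot be paired spot-for-spot."""


class ConfigurationError(ProtonQAError):
    """An error-model, tolerance or pipeline configuration is invalid."""


class ValidationError(ProtonQAError, ValueError):
    """A domain object violates its invariants."""
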