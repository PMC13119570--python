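"""Exception taxonomy shared across the package.

Every error a pipeline stage can raise maps either to a hard failure
(unreadable file, invalid configuration) or to a flagged measurement
record; the pipeline module decides which.
"""


class CoralmorphError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(CoralmorphError):
    """Degenerate or out-of-frame box/point geometry."""


class InvalidArgumentError(CoralmorphError, ValueError):
    """A precondition on a plain argument was violated."""


class ConfigurationError(CoralmorphError):
    """Unresolvable stage, unregistered backend id, or bad config value."""


class MissingCalibrationError(CoralmorphError):
    """No pixel-size metadata found and no override supplied."""


class AnisotropicCalibrationError(CoralmorphError):
    """Per-axis pixel sizes differ beyond the accepted tolerance."""


class InvalidCalibrationError(CoralmorphError):
    """Non-positive or otherwise unusable pixel size."""


class NoDetectionError(CoralmorphError):
    """No detection at or above the confidence threshold.

    Carries the best rejected confidence (None when there were no
    detections at all) so callers can distinguish 'nothing seen' from
    'seen but uncertain'.
    """

    def __init__(self, message: str, best_confidence: float | None = None):
        super().__init__(message)
        self.best_confidence = best_confidence


class InvalidSpecError(CoralmorphError):
    """Synthetic fixture specification violates its invariants."""


class JoinError(CoralmorphError):
    """Evaluation join failed; carries the offending image ids."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders = offenders or []
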