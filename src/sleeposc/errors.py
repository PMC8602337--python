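"""Exception hierarchy for the sleeposc pipeline.

Every stage raises a subclass of :class:`SleepOscError` so callers can
distinguish pipeline failures from programming errors.
"""


class SleepOscError(Exception):
    """Base class for all sleeposc errors."""


class InvalidSignalError(SleepOscError):
    """Signal contains non-finite samples or is otherwise unusable."""


class UnsupportedUpsamplingError(SleepOscError):
    """A filter spec requested a target rate above the source rate."""


class OutOfRangeError(SleepOscError):
    """An interval or timestamp lies outside the recording."""


class UnitError(SleepOscError):
    """A channel carries an unrecognised physical unit."""


class FormatError(SleepOscError):
    """A file does not match the declared format or montage."""


class DesignError(SleepOscError):
    """A synthetic cohort design is infeasible or inconsistent."""


class PlacementError(SleepOscError):
    """An injected event violates placement constraints."""


class CalibrationError(SleepOscError):
    """Relative-power calibration is impossible with the given data."""


class MontageError(SleepOscError):
    """A required channel is missing from the recording."""


class InsufficientDataError(SleepOscError):
    """Too little artifact-free data for a spectral estimate."""


class AlignmentError(SleepOscError):
    """Two series that must share a time base do not."""


class ParameterError(SleepOscError):
    """A numeric parameter is outside its admissible range."""


class NoSleepError(SleepOscError):
    """A hypnogram contains no sleep epochs."""


class IntegrityError(SleepOscError):
    """Metadata for one session is internally inconsistent."""


class EstimationError(SleepOscError):
    """A statistical model failed to converge."""


class ComparabilityError(SleepOscError):
    """Two model fits are not defined on the same data rows."""
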