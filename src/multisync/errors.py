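"""Exception hierarchy shared across the package."""


class MultisyncError(Exception):
    """Base class for all package errors."""


class ValidationError(MultisyncError, ValueError):
    """Invalid arguments, parameters, or configuration values."""


class ConstructionError(MultisyncError):
    """A model factory produced a system that fails its self-check."""


class ConfigError(MultisyncError):
    """Malformed or unknown keys in a run configuration."""


class IntegrationError(MultisyncError):
    """Numerical integration failed (non-finite or invalid state).

    Carries ``last_valid_time``, the latest time at which the state was
    still acceptable.
    """

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class RhythmError(MultisyncError):
    """Base class for trajectory-analysis failures."""


class SteadyStateError(RhythmError):
    """The analysed signal is flat: no rhythm to measure."""


class NoOscillationError(RhythmError):
    """Fewer than the minimum number of peaks were found."""


class InsufficientDataError(RhythmError):
    """Trajectory too short for the requested analysis."""


class NotFingerprintableError(RhythmError):
    """Attractor fingerprints are only defined for periodic regimes."""
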