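"""Exception hierarchy for rhbreath."""


class RHBreathError(Exception):
    """Base class for all rhbreath errors."""


class ConfigurationError(RHBreathError, ValueError):
    """A simulation or study configuration violates one of its bounds."""


class DecodeError(RHBreathError, ValueError):
    """A raw telemetry frame could not be decoded."""


class CSVFormatError(RHBreathError, ValueError):
    """A time-series CSV file violates the expected layout."""


class SingularFitError(RHBreathError, ValueError):
    """A least-squares fit is singular (e.g. constant regressor)."""
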