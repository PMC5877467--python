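"""Exception hierarchy for the pactkit pipeline."""


class PactError(Exception):
    """Base class for all pactkit errors."""


class FormatError(PactError):
    """A log file does not conform to the on-disk format (missing header,
    wrong column count, unparsable row)."""


class IntegrityError(PactError):
    """Data violates a structural invariant (non-monotonic time column,
    event end before start, overlapping sessions)."""


class ParameterError(PactError):
    """A filter or detector parameter is out of its valid range
    (e.g. cutoff at or above Nyquist)."""


class ModelError(PactError):
    """A forward-model constraint is violated (resonant frequency at or
    above the 16 MHz sampling cap, non-positive heart rate, negative
    transmitter-receiver distance, non-positive clock factor)."""


class ConfigError(PactError):
    """A simulation configuration value is invalid."""


class UndefinedStatisticError(PactError):
    """A summary statistic is undefined for the given input (fewer than two
    R-peaks in a heart-rate window, zero-variance series in a correlation)."""
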