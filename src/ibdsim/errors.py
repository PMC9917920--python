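"""Exception types shared across the package."""


class IBDSimError(Exception):
    """Base class for all package errors."""


class ConfigError(IBDSimError):
    """A configuration file or argument failed validation.

    The message lists every offending key.
    """


class InfeasibleMomentsError(IBDSimError):
    """Requested (mean, SD) pair is not attainable by a truncated normal
    on the given interval; the message names the violated bound."""


class LocalizationError(IBDSimError):
    """Seed population cannot support the requested marginal targets."""


class SeriesFormatError(IBDSimError):
    """A demand-series file does not match the declared CSV contract."""
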