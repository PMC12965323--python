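"""Exception hierarchy shared across the package."""


class MulticropError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MulticropError, ValueError):
    """A configuration mapping is invalid; the message names the offending key."""


class WorldFormatError(MulticropError, ValueError):
    """A world directory is missing a layer or a layer violates its schema."""


class NetworkError(MulticropError, ValueError):
    """The river network is not a forest (cycle or bad pointer)."""


class RequestOrderError(MulticropError, ValueError):
    """Allocation requests were not sorted by basin, priority class and rank."""


class CalibrationError(MulticropError, ValueError):
    """Country-level yield calibration is impossible for a country-crop."""


class RegressionError(MulticropError, ValueError):
    """Off-season regression cannot be fit (too few points or zero variance)."""
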