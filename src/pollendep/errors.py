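"""Exception hierarchy for the pollendep pipeline."""


class PollendepError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(PollendepError, ValueError):
    """A numeric parameter violates its constraint (e.g. non-positive area)."""


class GeometryError(PollendepError, ValueError):
    """A spot or structure does not fit on the leaf."""


class InfeasibleDesignError(PollendepError, ValueError):
    """A sampling design cannot be realised (too many points, no extreme cells)."""


class PackingError(PollendepError, RuntimeError):
    """Grains cannot be placed without overlap at the requested density."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} non-overlapping grains; "
            f"achieved {achieved} before placement failed"
        )


class CalibrationError(PollendepError, ValueError):
    """An image operation was attempted without a valid calibration."""


class InsufficientDataError(PollendepError, ValueError):
    """Too few measurements for the requested statistic."""


class CensoringNotAppliedError(PollendepError, ValueError):
    """Summary statistics requested on densities that still contain zeros."""


class ConfigError(PollendepError, ValueError):
    """Invalid run configuration; carries the offending key path."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key '{key}': {message}")
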