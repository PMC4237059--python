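"""Exception hierarchy."""


class HGFError(Exception):
    """Base class for all errors raised by this package."""


class ModelViolationError(HGFError):
    """An update produced a state outside the model's assumptions.

    Raised when a posterior precision is pushed to zero or below (large
    top-level step variance can do this) or when the volatility coupling
    exp(kappa*mu + omega) overflows.  Carries the trial index (1-based,
    None outside filtering) and the hierarchy level at which the
    violation occurred.
    """

    def __init__(self, message: str, trial: int | None = None, level: int | None = None):
        self.trial = trial
        self.level = level
        where = []
        if trial is not None:
            where.append(f"trial {trial}")
        if level is not None:
            where.append(f"level {level}")
        if where:
            message = f"{message} ({', '.join(where)})"
        super().__init__(message)


class RenormalizationError(HGFError):
    """Both mixture components underflowed when inferring the binary state."""


class InputFormatError(HGFError):
    """A trial-series file or value failed validation."""
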