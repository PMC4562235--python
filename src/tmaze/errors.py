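"""Exception hierarchy shared across the package."""


class TmazeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TmazeError):
    """A column mapping or analysis configuration is inconsistent."""


class ValidationError(TmazeError):
    """Input data violate a structural invariant (negative counts, bad tokens...)."""


class DegenerateTrialError(TmazeError):
    """A trial has no choosers, so a choice proportion is undefined."""


class InsufficientDesignError(TmazeError):
    """A score needs trials in both design arms but one arm is empty."""


class InsufficientGroupsError(TmazeError):
    """Variance decomposition needs at least two groups."""


class InsufficientDataError(TmazeError):
    """A statistical test received fewer values than it requires."""


class DegenerateDataError(TmazeError):
    """A statistical test received data with no usable variation."""
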