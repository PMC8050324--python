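"""Exception hierarchy for the analysis pipeline."""


class Ch4HystError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Ch4HystError, ValueError):
    """Input file does not follow the expected CSV dialect."""


class IntegrityError(Ch4HystError, ValueError):
    """Input data violate a structural invariant (duplicate/non-monotone dates)."""


class NoSeasonError(Ch4HystError):
    """No above-threshold day exists, or the longest run is shorter than required."""


class AnchorError(Ch4HystError):
    """The flux anchor at the seasonal temperature maximum cannot be determined."""


class ConstraintError(Ch4HystError, ValueError):
    """Inconsistent fixed-point constraints passed to a constrained fit."""


class DegenerateFitError(Ch4HystError):
    """The free design is rank deficient or a branch is empty / unidentifiable."""


class InsufficientDataError(Ch4HystError):
    """Fewer data points than the operation's stated minimum."""


class UndefinedAreaError(Ch4HystError):
    """Both fitted branch curves are identically zero; H_A has no normalization."""


class StabilityError(Ch4HystError):
    """Mechanistic substrate-pool integration diverged."""
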