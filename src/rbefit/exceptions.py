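"""Exception hierarchy for rbefit.

Everything raised on purpose derives from :class:`RbefitError` so callers
(and the CLI) can catch domain failures without swallowing programming
errors.
"""


class RbefitError(Exception):
    """Base class for all rbefit domain errors."""


class DataFormatError(RbefitError):
    """A CSV file does not match either recognised dialect."""


class DataValidationError(RbefitError, ValueError):
    """Input values violate a domain invariant (negative dose, bad SD...)."""


class UnderdeterminedFitError(RbefitError):
    """Fewer dose groups than free parameters plus one."""


class DegenerateDataError(RbefitError):
    """Data carry no signal to fit (e.g. all group means zero)."""


class DegenerateVarianceError(RbefitError):
    """Pooled within-group variance is zero; pure-error tests are undefined.

    Add replicate noise or supply raw counts with within-group spread.
    """


class InversionError(RbefitError):
    """A dose-response curve could not be inverted at the requested effect."""


class BootstrapFailureError(RbefitError):
    """Too many bootstrap replicates failed to fit (> 20%)."""
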