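"""Exception hierarchy shared across the package.

Every error a caller is expected to handle derives from :class:`RootGrnError`,
so the CLI can map user-facing failures to exit code 1 and anything else to 2.
"""


class RootGrnError(Exception):
    """Base class for all rootgrn errors."""


class InvalidArgument(RootGrnError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class ParseError(RootGrnError):
    """A TSV/YAML input is malformed; the message names the offending line."""


class EmptyDenominator(RootGrnError, ZeroDivisionError):
    """A precision/fraction was requested over an empty edge set."""


class CalibrationError(RootGrnError):
    """The requested overexpression fold is unreachable."""


class IntegrationError(RootGrnError):
    """The ODE solver failed or the state left the nonnegative quadrant."""


class AnalysisError(RootGrnError):
    """A numerical analysis (root finding, sensitivity) could not complete."""
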