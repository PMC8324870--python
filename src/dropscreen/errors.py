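"""Exception hierarchy shared across the package.

Validation failures (bad manifests, inconsistent matrices, degenerate
score distributions) raise :class:`ValidationError`; malformed input
files raise :class:`ParseError`. Both derive from ``ValueError`` so
callers that do not care about the distinction can catch one type.
"""


class DropscreenError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(DropscreenError):
    """An input violated a structural invariant (duplicates, mismatched
    dimensions, empty sample, degenerate distribution, ...)."""


class ParseError(DropscreenError):
    """A file could not be parsed; the message names the offending line."""
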