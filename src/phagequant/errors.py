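"""Exception hierarchy shared across the package.

All errors derive from :class:`PhagequantError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
malformed files, bad data values, insufficient curve coverage, and model-fit
failures.
"""


class PhagequantError(Exception):
    """Base class for all errors raised by phagequant."""


class FormatError(PhagequantError):
    """A table is structurally malformed (missing column, unknown layout)."""


class DataError(PhagequantError):
    """A table parsed but contains invalid values (negative OD, duplicates)."""


class CoverageError(PhagequantError):
    """A growth curve does not span the region an operation requires."""


class FitError(PhagequantError):
    """A model fit failed or produced nonsensical parameters."""

    def __init__(self, message, *, rss=None, last_params=None):
        super().__init__(message)
        self.rss = rss
        self.last_params = last_params


class NonIdentifiableError(FitError):
    """The data cannot constrain the model (flat or strictly decaying curve)."""
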