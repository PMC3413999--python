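"""Exception hierarchy shared across the package."""


class CellDriftError(Exception):
    """Base class for all package errors."""


class FormatError(CellDriftError):
    """A file or table does not conform to the canonical track dialect."""


class ValidationError(CellDriftError):
    """A domain object violates one of its invariants."""


class FitError(CellDriftError):
    """A regression cannot be computed (too few rows, degenerate design)."""
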