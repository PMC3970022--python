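"""Exception hierarchy for the mtai package.

All package-specific errors derive from :class:`MtaiError` so callers can
catch everything with one clause; the subclasses distinguish malformed input
(:class:`ValidationError`), geometric defects in a traced contour
(:class:`GeometryError`), and mathematically undefined index values
(:class:`DomainError`).
"""


class MtaiError(Exception):
    """Base class for all errors raised by mtai."""


class ValidationError(MtaiError, ValueError):
    """Input fails a structural or anatomical invariant."""


class GeometryError(ValidationError):
    """A traced contour is geometrically unusable (e.g. self-intersecting)."""


class DomainError(MtaiError, ValueError):
    """An index is mathematically undefined for the given areas."""


class TableValidationError(ValidationError):
    """One or more rows of an areas table failed validation.

    Attributes
    ----------
    row_errors : list of (int, str)
        1-based data-row numbers (header excluded) with a message each.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = [f"row {row}: {msg}" for row, msg in self.row_errors]
        super().__init__(
            "areas table validation failed:\n  " + "\n  ".join(lines)
        )
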