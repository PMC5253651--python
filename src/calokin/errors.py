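"""Exception hierarchy.

All package-raised errors derive from :class:`CalokinError` so callers can
catch everything with one clause; the subclasses distinguish bad inputs
(user-correctable), degenerate inputs (structurally valid but carrying no
usable signal), fit failures and file-parsing problems. The CLI maps these
onto exit codes (2 for validation, 3 for fit failure).
"""

from __future__ import annotations


class CalokinError(Exception):
    """Base class for all errors raised by calokin."""


class InvalidInputError(CalokinError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(CalokinError, ValueError):
    """Input is structurally valid but leaves nothing to analyse
    (e.g. zero total heat, induction trim removing every point)."""


class FitFailureError(CalokinError, RuntimeError):
    """A nonlinear fit did not converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class ParseError(CalokinError, ValueError):
    """A data file does not conform to the documented dialect."""

    def __init__(self, message: str, path=None, line: int | None = None,
                 field: str | None = None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if field is not None:
            loc.append(f"field '{field}'")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.path = path
        self.line = line
        self.field = field
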