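"""Exception hierarchy."""


class CarpSimError(Exception):
    """Base class for all package errors."""


class DomainError(CarpSimError, ValueError):
    """A value outside the modelled domain (age, sex, state or event code)."""


class IncompleteTableError(CarpSimError, KeyError):
    """A risk-table lookup hit a cell that was never provided."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep messages readable
        return str(self.args[0]) if self.args else ""


class TableValidationError(CarpSimError, ValueError):
    """A risk table violates its invariants (range, completeness or
    competing-risk sums)."""

    def __init__(self, violations):
        self.violations = list(violations)
        preview = "; ".join(self.violations[:5])
        more = len(self.violations) - 5
        if more > 0:
            preview += f"; ... ({more} more)"
        super().__init__(f"invalid risk table: {preview}")


class ParseError(CarpSimError, ValueError):
    """A CSV/JSON input file could not be parsed; names the offending row."""


class ConfigError(CarpSimError, ValueError):
    """Invalid synthetic-data or scenario configuration."""
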