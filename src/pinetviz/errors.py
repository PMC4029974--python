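"""Exception hierarchy for pinetviz.

All package errors derive from :class:`PinvError` so callers (and the CLI)
can distinguish data problems from programming errors.
"""


class PinvError(Exception):
    """Base class for all pinetviz errors."""


class ParseError(PinvError):
    """A dataset file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message} ({', '.join(loc)})" if loc else message)
        self.line = line
        self.column = column


class QueryError(PinvError):
    """Invalid filter condition or query (unknown field, accession, operator)."""


class RuleError(PinvError):
    """A styling rule failed to compile (bad action params or type mismatch)."""


class LayoutError(PinvError):
    """Layout preconditions violated (empty subnetwork, bad parameters)."""


class RenderError(PinvError):
    """Rendering/export failure (missing position, unknown column)."""


class SessionError(PinvError):
    """Invalid session operation, history entry, or state JSON."""
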