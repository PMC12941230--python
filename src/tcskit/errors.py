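"""Exception hierarchy shared across the toolkit.

The CLI maps these onto exit codes: :class:`ParseError` (malformed input
files or descriptors) exits 2, :class:`ValidationError` (well-formed input
violating a model invariant) exits 3.
"""

from __future__ import annotations


class TcsKitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(TcsKitError):
    """A file or descriptor could not be parsed.

    Carries the offending line number when the source is a file.
    """

    def __init__(self, message: str, line: int | None = None, source: str | None = None):
        self.line = line
        self.source = source
        prefix = ""
        if source is not None:
            prefix += f"{source}:"
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class ValidationError(TcsKitError):
    """Well-formed input violates a structural or biological invariant."""


class ReferenceMismatchError(ValidationError):
    """A variant's stated reference bases disagree with the supplied sequence."""

    def __init__(self, position: int, expected: str, found: str):
        self.position = position
        self.expected = expected
        self.found = found
        super().__init__(
            f"reference disagreement at c.{position}: descriptor states "
            f"{expected!r} but sequence has {found!r}"
        )


class NotApplicableError(TcsKitError):
    """The requested operation does not apply to this input class."""
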