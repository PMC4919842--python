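"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`SemSchemaError`, so callers (and the CLI) can distinguish expected
validation failures from genuine bugs.
"""

from __future__ import annotations


class SemSchemaError(Exception):
    """Base class for all package errors."""


class ValidationError(SemSchemaError):
    """An input violates a data-model rule (empty name, illegal value, ...)."""


class RegistryLookupError(SemSchemaError, KeyError):
    """An unknown semantic type or modifier class was requested."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class ConflictError(ValidationError):
    """An operation would invalidate existing state (e.g. retyping a concept
    whose current modifier assignments are not allowed under the new type)."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders: list[str] = offenders or []


class ParseError(SemSchemaError):
    """Malformed textual input (lexicon row, numeric range, request)."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class IntegrityError(SemSchemaError):
    """Referential-integrity failure in a terminology fixture."""


class DialectError(SemSchemaError):
    """An OWL document does not use the schema-ontology dialect vocabulary."""


class ExportError(SemSchemaError):
    """A schema cannot be exported in its current state."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders: list[str] = offenders or []


class UnmappedSemanticTypeWarning(UserWarning):
    """A terminology record's source semantic type has no mapping onto the
    registry's semantic types; the concept is left untyped."""
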