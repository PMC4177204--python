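"""Exception and warning hierarchy shared by all vaekb modules."""


class VaekbError(Exception):
    """Base class for all vaekb errors."""


class DuplicateTermError(VaekbError):
    """A class id or label is already registered in the knowledge base."""


class DanglingReferenceError(VaekbError):
    """An id refers to a class or property that is not registered."""


class CycleError(VaekbError):
    """An operation would create a cycle in the asserted subclass graph."""


class SchemaError(VaekbError):
    """A tabular input is missing required columns or has extra ones."""


class RowError(VaekbError):
    """A data row could not be parsed; carries the 1-based row number."""

    def __init__(self, row_number: int, message: str):
        self.row_number = row_number
        super().__init__(f"row {row_number}: {message}")


class ParseError(VaekbError):
    """A textual expression or document could not be parsed."""


class RangeError(VaekbError):
    """A numeric value is outside its permitted range."""


class OverlapError(VaekbError):
    """Two age intervals for the same (vaccine, AE) pair overlap."""


class ConflictError(VaekbError):
    """Rows for the same (vaccine, AE) pair disagree on a fixed attribute."""


class CapacityError(VaekbError):
    """The id serial space is exhausted."""


class UnsupportedAxiomError(VaekbError):
    """An axiom uses a construct outside the supported EL fragment."""


class ClassificationNotRunError(VaekbError):
    """An operation requires classify() to have been run first."""


class EmptyKBError(VaekbError):
    """The knowledge base lacks the content required by an analysis."""


class QueryParseError(ParseError):
    """A query string is outside the supported subset; carries a position."""

    def __init__(self, position: int, message: str):
        self.position = position
        super().__init__(f"at position {position}: {message}")


class ConfigError(VaekbError):
    """A generator configuration is inconsistent or impossible."""


class FixtureNotFoundError(VaekbError):
    """An unknown bundled fixture name was requested."""


class ValidationWarning(UserWarning):
    """Non-fatal inconsistency detected while validating template input."""
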