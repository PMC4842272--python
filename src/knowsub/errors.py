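"""Exception hierarchy.

Every error raised by the package derives from :class:`KnowsubError` so
callers (and the CLI) can catch the whole family in one clause.
"""


class KnowsubError(Exception):
    """Base class for all knowsub errors."""


class ConflictError(KnowsubError):
    """An entity with the same identity already exists."""


class NotFoundError(KnowsubError):
    """A referenced substance, question, decision or module does not exist."""


class ValidationError(KnowsubError):
    """An input value violates an invariant (empty record, bad answer type, ...)."""


class QuerySyntaxError(KnowsubError):
    """A SPARQL query failed to parse; carries the parser's position message."""


class ParseError(KnowsubError):
    """A knowledge-base or Turtle file failed to parse.

    ``line`` is the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LinkError(ParseError):
    """A module references a question/decision id that is not declared."""


class StructureError(KnowsubError):
    """A hierarchy or workflow violates its structural invariants (cycle, ...)."""


class RegistryError(KnowsubError):
    """The module registry is ill-formed (dependency cycle, duplicate ids)."""


class EvaluationError(KnowsubError):
    """A condition could not be evaluated (e.g. numeric compare on text)."""


class ChronologyError(KnowsubError):
    """A fact was recorded with a timestamp earlier than existing history."""


class ViewError(KnowsubError):
    """A dynamic view failed to execute; names the offending view."""


class FormatError(KnowsubError):
    """A tabular input file does not have the expected header/layout."""
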