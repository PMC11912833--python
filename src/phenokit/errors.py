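"""Exception hierarchy shared across the package."""


class PhenokitError(Exception):
    """Base class for all package errors."""


class ParseError(PhenokitError):
    """Raised when an input document (OBO, OBO-Graph JSON, Manchester text,
    template YAML, SSSOM TSV) does not conform to the supported subset.

    ``position`` carries a character or line position when known.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class UnknownTermError(PhenokitError):
    """A CURIE or label could not be resolved against the loaded graphs."""


class ValidationError(PhenokitError):
    """Structured content violates an invariant (undeclared template slot,
    out-of-range filler, cyclic hierarchy, missing prefix, ...)."""
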