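"""Exception hierarchy for the snowball2 package."""


class SnowballError(Exception):
    """Base class for all snowball2 errors."""


class InvalidInputError(SnowballError):
    """Malformed sentence, entity or configuration input."""


class InvalidRelationError(SnowballError):
    """A relation violates a structural constraint (overlapping slot
    entities, missing slots, entities outside the sentence)."""


class IncomparablePhrasesError(SnowballError):
    """Two phrases do not share a pseudocluster layout and cannot be
    compared by the element-wise similarity."""


class AnnotationError(SnowballError):
    """Invalid selection during supervised annotation."""


class ConfigError(SnowballError):
    """Invalid synthetic-corpus or hyperparameter configuration."""


class ModelFormatError(SnowballError):
    """A serialized model archive is unreadable or has an incompatible
    format version."""


class SentenceValidationError(InvalidInputError):
    """A serialized sentence failed validation; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
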