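"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage errors exit 1, validation and
format errors exit 2, stage failures exit 3.
"""


class TelncrnaError(Exception):
    """Base class for all package errors."""


class ValidationError(TelncrnaError):
    """An input object or value violates a documented invariant."""


class FormatError(ValidationError):
    """A file does not conform to its declared dialect."""


class SchemaError(ValidationError):
    """A tabular input is missing required columns or labels."""


class GenerationError(TelncrnaError):
    """The synthetic-data generator cannot satisfy its configuration."""


class StageError(TelncrnaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
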