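"""Exception hierarchy for the package."""


class GFResponseError(Exception):
    """Base class for all package errors."""


class SchemaError(GFResponseError):
    """A table is missing required columns."""


class ParseError(GFResponseError):
    """A cell could not be parsed (carries the offending row index in the message)."""


class ValidationError(GFResponseError):
    """A table parsed but violates a domain invariant."""


class ConfigError(GFResponseError):
    """A configuration value is out of its allowed domain."""


class PipelineError(GFResponseError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
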