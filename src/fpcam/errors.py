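"""Exception hierarchy shared across the package."""


class FpcamError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FpcamError):
    """An input table is missing a required column or has an unusable header."""


class ValidationError(FpcamError):
    """Row-level content violates a contract (e.g. votes exceed the total)."""


class PipelineError(FpcamError):
    """A pipeline stage failed; the message names the stage."""
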