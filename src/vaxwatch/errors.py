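"""Exception hierarchy shared across the pipeline stages."""


class VaxwatchError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(VaxwatchError):
    """A record violates the post schema (missing field, bad type, bad value)."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateIdError(SchemaError):
    """Two records share a post_id."""


class ConfigError(VaxwatchError):
    """A query spec, rule set, or simulation config is invalid."""


class UndefinedDenominatorError(VaxwatchError):
    """A proportion was requested over an empty group."""


class DegenerateTableError(VaxwatchError):
    """A contingency table has a zero margin; the chi-square test is undefined."""


class SampleSizeError(VaxwatchError):
    """Requested sample size exceeds the eligible pool."""


class AlignmentError(VaxwatchError):
    """Two label maps do not cover the same posts."""


class LinkageError(VaxwatchError):
    """A retweet record does not point at the post it was claimed to share."""


class PartitionError(VaxwatchError):
    """Groups that must be disjoint overlap."""


class LookupError_(VaxwatchError):
    """An unknown theme or category name was referenced."""


class PipelineStageError(VaxwatchError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
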