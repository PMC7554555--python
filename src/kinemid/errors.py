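"""Exception hierarchy shared across the pipeline stages.

Validation failures (bad parameters, bad config, malformed data) derive from
:class:`ValidationError`; failures while executing an otherwise valid request
derive from :class:`RuntimeStageError`.  The CLI maps these to exit codes 1
and 2 respectively.
"""


class KinemidError(Exception):
    """Base class for all package errors."""


class ValidationError(KinemidError):
    """Invalid parameters, config, or input schema."""


class ParameterError(ValidationError):
    """A scalar parameter is out of its allowed range."""


class ConfigError(ValidationError):
    """A run configuration failed strict-schema validation."""


class SchemaError(ValidationError):
    """Tabular/waveform input does not match the expected layout."""


class RuntimeStageError(KinemidError):
    """A pipeline stage failed on valid input."""


class SegmentationError(RuntimeStageError):
    """Kick start/end events could not be located."""


class SplitError(RuntimeStageError):
    """The protocol structure is too small for the requested split scheme."""


class TaskError(RuntimeStageError):
    """A classification task cannot be built or run on the given data."""


class InsufficientDataError(RuntimeStageError):
    """Too few subjects/kicks for the requested statistical comparison."""
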