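"""Exception hierarchy shared across the pipeline."""


class MetaboStageError(Exception):
    """Base class for all package errors."""


class FormatError(MetaboStageError):
    """A file or table does not have the required layout."""


class ValidationError(MetaboStageError):
    """Data violates a container invariant."""


class ConfigError(MetaboStageError):
    """An analysis parameter is out of its admissible range."""
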