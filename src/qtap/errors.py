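"""Exception hierarchy shared across the pipeline.

Three error families map onto distinct CLI exit codes so that shell callers
can tell a malformed file (format), a bad parameter (configuration) and an
internally inconsistent dataset (data integrity) apart.
"""


class QtapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(QtapError):
    """A file does not conform to the documented tabular layout."""

    exit_code = 2


class ConfigurationError(QtapError):
    """A parameter or config field is outside its documented range."""

    exit_code = 3


class DataIntegrityError(QtapError):
    """A dataset violates an invariant (duplicates, missing partners, ...)."""

    exit_code = 4


class PipelineError(QtapError):
    """A pipeline stage failed; message carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
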