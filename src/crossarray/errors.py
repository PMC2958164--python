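"""Exception hierarchy shared across the pipeline."""


class CrossArrayError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CrossArrayError):
    """Malformed or internally inconsistent input file."""


class ParameterError(CrossArrayError):
    """Invalid argument, margin, or configuration value."""


class DegenerateInputError(CrossArrayError):
    """Structurally valid input that carries no usable signal."""


class EmptyResultError(CrossArrayError):
    """An operation produced an empty result where downstream stages need data."""


class PipelineStageError(CrossArrayError):
    """A pipeline stage failed; wraps the original error with the stage name."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
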