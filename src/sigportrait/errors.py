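"""Exception hierarchy shared across the package."""


class SigPortraitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SigPortraitError):
    """A user-supplied configuration value is invalid (bad column name, bad scheme...)."""


class ParseError(SigPortraitError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ManifestError(SigPortraitError):
    """The study manifest violates a constraint (e.g. >2 datasets per study)."""


class EmptyInputError(SigPortraitError):
    """An input file or collection contained no usable rows."""


class PipelineStageError(SigPortraitError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, source: str, original: BaseException):
        self.stage = stage
        self.source = source
        self.original = original
        super().__init__(f"stage '{stage}' failed on {source!r}: {original}")
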