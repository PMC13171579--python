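"""Exception types shared across the package."""


class DbslfpError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DbslfpError):
    """A run or design configuration is invalid or incomplete."""


class ValidationError(DbslfpError):
    """Data passed to an operation violates its contract."""


class StageError(DbslfpError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause!r}")
        self.stage = stage
        self.cause = cause
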