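"""Exception hierarchy shared across the package.

CLI exit-code mapping: ConfigurationError -> 2, DataError -> 3,
StageError (runtime failure inside a pipeline stage) -> 4.
"""


class ImflightError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ImflightError):
    """Invalid configuration value or inconsistent config combination."""


class DataError(ImflightError):
    """Invalid or unreadable input data."""


class StageError(ImflightError):
    """A pipeline stage failed at runtime; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
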