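"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataContractError -> 3.
"""


class TertscapeError(Exception):
    """Base class for all package errors."""


class ConfigError(TertscapeError):
    """Invalid configuration: bad threshold, missing path, malformed option."""

    exit_code = 2


class DataContractError(TertscapeError):
    """Input data violates a documented contract (bad enum value, negative
    count, duplicate identifier, missing control group, ...)."""

    exit_code = 3


class StageError(TertscapeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
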