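"""Exception hierarchy for the pipeline."""


class CRSigError(Exception):
    """Base class for all package errors."""


class ConfigError(CRSigError, ValueError):
    """Invalid configuration or parameter combination."""


class FormatError(CRSigError, ValueError):
    """Malformed input file."""


class DegenerateInputError(CRSigError, ValueError):
    """Input whose statistic is undefined (zero spread, constant ranks, ...)."""


class StageError(CRSigError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
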