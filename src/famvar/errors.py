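"""Exception hierarchy for famvar."""


class FamvarError(Exception):
    """Base class for all famvar errors."""


class ConfigError(FamvarError):
    """Invalid configuration: missing columns, bad switch values, absent paths."""


class DataError(FamvarError):
    """Inconsistent input data: conflicting duplicates, unknown references."""


class ParameterError(FamvarError):
    """Infeasible parameter values (e.g. sample size larger than universe)."""


class DegenerateRangeError(FamvarError):
    """All raw scores identical: min-max normalization undefined."""


class PipelineError(FamvarError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
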