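"""Exception types shared across the package."""


class MirDrugSurvError(Exception):
    """Base class for all package errors."""


class NoValidThreshold(MirDrugSurvError):
    """Raised when a feature cannot be binarized (constant or too few values)."""


class PipelineError(MirDrugSurvError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
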