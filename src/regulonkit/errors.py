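"""Exception hierarchy shared across the pipeline."""


class RegulonKitError(Exception):
    """Base class for all package errors."""


class InputError(RegulonKitError, ValueError):
    """Invalid user-supplied value (bad counts, NaN scores, unknown leaf...)."""


class AlignmentError(RegulonKitError, ValueError):
    """Incompatible motif/site dimensions; user must pre-align collections."""


class ConfigurationError(RegulonKitError, ValueError):
    """Invalid run configuration (missing sites, no usable references...)."""


class ModelError(RegulonKitError, ValueError):
    """A statistical model cannot be fitted (zero windows, zero variance)."""


class PipelineError(RegulonKitError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
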