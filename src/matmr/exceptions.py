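"""Exception hierarchy shared across the package."""


class MatmrError(Exception):
    """Base class for all package errors."""


class FormatError(MatmrError):
    """A summary-statistic file cannot be parsed (e.g. a mandatory column is missing)."""


class ParameterError(MatmrError, ValueError):
    """A user-supplied parameter is outside its admissible range."""


class ConfigurationError(MatmrError):
    """A simulation or pipeline configuration is internally inconsistent."""


class DegenerateSnpError(MatmrError, ValueError):
    """A SNP is monomorphic (allele frequency 0 or 1) where variation is required."""


class WeakInstrumentError(MatmrError):
    """The instrument carries no first-stage association with the exposure."""


class EstimationError(MatmrError):
    """An estimator cannot be computed on the provided instrument set."""


class StageError(MatmrError):
    """A pipeline stage failed; the stage name is carried in the message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
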