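"""Exception hierarchy shared across the package."""


class NeoscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeoscreenError):
    """Invalid configuration: bad simulation parameters, unknown batch or analyte."""


class CohortParseError(NeoscreenError):
    """A cohort or rules file violates the expected schema or an invariant."""


class StratumError(NeoscreenError):
    """A normalization stratum is too small to yield a stable median."""


class FeatureError(NeoscreenError):
    """Feature construction failed (degenerate denominator, feature mismatch)."""


class CalibrationError(NeoscreenError):
    """No candidate model attains the required training sensitivity, or a
    disease group lacks the training positives needed to calibrate a cutoff."""


class UnsupportedScenarioError(NeoscreenError):
    """A requested simulation scenario is not expressible for the given group."""


class PipelineStageError(NeoscreenError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
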