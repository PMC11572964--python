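"""Exception hierarchy for the coolscale pipeline.

Validation problems (bad configuration, malformed inputs) and computation
problems (degenerate designs, failed fits) are kept on separate branches so
the CLI can map them to distinct exit codes.
"""


class CoolscaleError(Exception):
    """Base class for all package errors."""


class ValidationError(CoolscaleError):
    """A configuration or input failed its preconditions."""


class ConfigurationError(ValidationError):
    """A simulation or run configuration field is invalid."""


class AlignmentError(ValidationError):
    """LST and canopy rasters do not cover the same footprint."""


class ResolutionRatioError(ValidationError):
    """Fine canopy resolution does not evenly divide the base resolution."""


class CoverRangeError(ValidationError):
    """Fractional cover values fall outside [0, 1]."""


class ComputationError(CoolscaleError):
    """A computation failed on valid inputs."""


class EstimationError(ComputationError):
    """A per-scale CE regression could not be estimated."""


class FitError(ComputationError):
    """A power-law or quadratic scaling fit could not be computed."""


class PredictionError(ComputationError):
    """A whole-city prediction was requested from an unsuitable fit."""


class JoinError(ValidationError):
    """Per-date exponents and weather records could not be matched."""


class PipelineError(ComputationError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
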