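"""Exception types shared across the package."""


class VaxdceError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(VaxdceError, ValueError):
    """An attribute or study specification violates its invariants."""


class DesignInfeasibleError(VaxdceError, ValueError):
    """No orthogonal main-effects array exists for the requested run size."""


class ValidationError(VaxdceError, ValueError):
    """A choice table violates the long-format schema invariants."""


class IdentifiabilityError(VaxdceError, ValueError):
    """A model covariate does not vary in the data."""


class UndefinedWTPError(VaxdceError, ValueError):
    """Willingness to pay is undefined (zero price coefficient)."""


class ScenarioError(VaxdceError, ValueError):
    """An uptake scenario is invalid (e.g. includes the price attribute)."""


class ConfigurationError(VaxdceError, ValueError):
    """A pipeline configuration references missing columns or paths."""


class PipelineStageError(VaxdceError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
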