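"""Exception hierarchy for the circabp pipeline."""


class CircabpError(Exception):
    """Base class for all circabp errors."""


class InvalidConfigError(CircabpError, ValueError):
    """A configuration value is out of its admissible range."""


class DomainError(CircabpError, ValueError):
    """A physical quantity left its admissible domain (e.g. glc <= 0)."""


class IntegrationFailureError(CircabpError, RuntimeError):
    """The ODE solver failed; ``t_failure`` records where."""

    def __init__(self, message: str, t_failure: float | None = None):
        super().__init__(message)
        self.t_failure = t_failure


class AlignmentError(CircabpError, ValueError):
    """Dataset and trajectory are not on the same time grid."""


class FitFailureError(CircabpError, RuntimeError):
    """No optimizer start produced an integrable candidate."""


class WeightingDomainError(CircabpError, ValueError):
    """A zero standard deviation makes the FIM weighting undefined."""


class SingularFIMError(CircabpError, RuntimeError):
    """FIM numerically singular; carries a null-space basis."""

    def __init__(self, message: str, null_space=None, condition_number=None):
        super().__init__(message)
        self.null_space = null_space
        self.condition_number = condition_number


class DegenerateSampleError(CircabpError, ValueError):
    """A statistical test received a degenerate (constant) sample."""
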