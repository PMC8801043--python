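"""Exception types raised across the package."""


class ScarnetError(Exception):
    """Base class for all package-specific errors."""


class ParameterValidationError(ScarnetError):
    """A parameter value violates its physical constraints."""


class StateValidityError(ScarnetError):
    """A state field violates nonnegativity/finiteness/strain bounds."""


class UnstableParametersError(ScarnetError):
    """Parameter set violates the linear-stability admissibility condition."""


class SolverError(ScarnetError):
    """Fatal condition inside the finite-element solver (singular system,
    mesh tangling, excessive negative-mass clipping)."""


class StepFailureError(SolverError):
    """Picard iteration failed to converge within the iteration budget."""

    def __init__(self, message, residual_history=None, step=None):
        super().__init__(message)
        self.residual_history = residual_history or []
        self.step = step


class GeometryError(ScarnetError):
    """Invalid wound-edge geometry (nonpositive edge position)."""


class ConfigurationError(ScarnetError):
    """Invalid range/scenario/network configuration."""


class TrainingError(ScarnetError):
    """Training diverged (non-finite loss)."""

    def __init__(self, message, epoch=None):
        super().__init__(message)
        self.epoch = epoch


class ScenarioError(ScarnetError):
    """Monte-Carlo scenario cannot produce admissible draws."""
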