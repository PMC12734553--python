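"""Exception hierarchy for the two-compartment carrier model."""


class FlipkinError(Exception):
    """Base class for all package errors."""


class ParameterError(FlipkinError, ValueError):
    """Invalid model parameters."""


class InconsistentInitialConditionError(FlipkinError, ValueError):
    """Initial condition does not match the stated total cargo M/N."""


class BoundaryOccupancyError(FlipkinError, ValueError):
    """Equilibrium occupancy would sit at p=0/1 or q=0/1 (M=0 or full system)."""


class InfeasibleEquilibriumError(FlipkinError, ValueError):
    """No detailed-balance root inside (0,1)^2."""


class NumericalUnderflowError(FlipkinError, ArithmeticError):
    """A required probability mass underflowed even in log space."""


class ConvergenceError(FlipkinError, RuntimeError):
    """The ODE integrator failed to converge."""


class DegenerateDeltaError(FlipkinError, ValueError):
    """A delta distribution was requested where a density is needed (t <= 0)."""


class ConfigError(FlipkinError, ValueError):
    """Malformed run configuration."""
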