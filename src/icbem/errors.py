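"""Exception hierarchy for the icbem package."""


class IcbemError(Exception):
    """Base class for all package errors."""


class ParameterError(IcbemError, ValueError):
    """Invalid geometry or solver parameters."""


class AssemblyError(IcbemError, RuntimeError):
    """Matrix assembly failed (e.g. coincident tile centers)."""


class ProximityError(IcbemError, ValueError):
    """A source charge or evaluation point is too close to a singularity."""


class ConvergenceError(IcbemError, RuntimeError):
    """Iterative solver failed to converge within the sweep budget."""

    def __init__(self, message: str, final_update: float, iterations: int):
        super().__init__(message)
        self.final_update = final_update
        self.iterations = iterations


class NumericalError(IcbemError, RuntimeError):
    """Linear algebra failure (singular or severely ill-conditioned system)."""


class ConfigurationError(IcbemError, ValueError):
    """Inconsistent run configuration or scenario setup."""
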