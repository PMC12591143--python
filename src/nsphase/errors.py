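"""Exception hierarchy shared across the package."""


class NSPhaseError(Exception):
    """Base class for all package-specific errors."""


class CompositionInfeasibleError(NSPhaseError, ValueError):
    """A mixture composition violates a stoichiometric feasibility bound."""


class UndefinedOrderParameterError(NSPhaseError, ValueError):
    """Order parameter undefined: a sticky-end family is absent (F_A in {0, 1} with F_ab > 0)."""


class DegenerateMappingError(NSPhaseError, ValueError):
    """The chi <-> order-parameter mapping is degenerate (c1 = 0 or zero slope)."""


class SimulationUnstableError(NSPhaseError, RuntimeError):
    """Cahn-Hilliard integration produced non-finite values."""

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(f"non-finite field values at step {step_index}")


class DomainError(NSPhaseError, ValueError):
    """Arguments lie outside the physical domain (e.g. the composition simplex)."""


class GeometryError(NSPhaseError, ValueError):
    """Requested doublet geometry is not constructible."""


class UnfittableError(NSPhaseError, ValueError):
    """Interface/contour geometry cannot be fitted (too few pixels, no intersection...)."""


class SingularConfigurationError(NSPhaseError, ValueError):
    """Contact angles at a singular point of the Neumann relations (theta_A+theta_B = k*pi)."""


class ConfigError(NSPhaseError, ValueError):
    """A pipeline configuration file failed schema validation."""


class CapacityError(NSPhaseError, RuntimeError):
    """Droplet placement on the synthetic canvas failed after bounded retries."""
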