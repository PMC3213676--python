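"""Exception hierarchy shared across the package."""


class EpilandError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EpilandError, ValueError):
    """A state variable is outside the model's domain (negative or non-finite)."""


class ParameterError(EpilandError, ValueError):
    """A parameter set violates a model invariant (e.g. K_D = 0 with a nonzero fold)."""


class IntegrationError(EpilandError, RuntimeError):
    """Numerical integration failed (divergence or non-finite rates)."""


class ConfigurationError(EpilandError, RuntimeError):
    """A search or run configuration cannot produce a result (e.g. no roots found)."""


class AlignmentError(EpilandError, RuntimeError):
    """Trajectory alignment is impossible (disconnected basin adjacency graph)."""


class NoSharedBoundaryError(EpilandError, RuntimeError):
    """Two basins share no boundary on the surface grid.

    Carries the labels of intermediate basins adjacent to both, so callers can
    reason about indirect (multi-hop) transition routes.
    """

    def __init__(self, basin_a, basin_b, intermediates):
        self.basin_a = basin_a
        self.basin_b = basin_b
        self.intermediates = list(intermediates)
        msg = (
            f"basins {basin_a} and {basin_b} share no boundary on the grid; "
            f"intermediate basin(s): {self.intermediates or 'none found'}"
        )
        super().__init__(msg)
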