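"""Exception hierarchy for afmech."""


class AfmechError(Exception):
    """Base class for all afmech errors."""


class InvalidDeformationError(AfmechError):
    """Deformation gradient is not admissible (e.g. det F <= 0)."""


class ConfigurationError(AfmechError):
    """Inconsistent material/solver configuration (e.g. penalty mode without D)."""


class OverflowGuardError(AfmechError):
    """Fiber exponent K2 * Ebar**2 exceeds the floating-point overflow guard."""


class SolverError(AfmechError):
    """A protocol boundary-value solve failed to converge."""


class FitFailureError(AfmechError):
    """No optimizer start converged, or the data cannot identify the free parameters."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
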