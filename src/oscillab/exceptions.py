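"""Exception hierarchy for oscillab."""


class OscillabError(Exception):
    """Base class for all oscillab errors."""


class ValidationError(OscillabError, ValueError):
    """Invalid input (nonpositive parameter, wrong dimension, ...)."""


class InfeasibleError(OscillabError):
    """The requested bifurcation cannot occur for these parameters."""


class ConvergenceError(OscillabError):
    """A root finder or iteration failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class HopfNotFoundError(OscillabError):
    """No sign change of the bifurcation function in the search bracket."""


class DegenerateCandidateError(OscillabError):
    """D_{m-1} vanishes but the remaining simple-Hopf conditions fail."""


class NoCycleError(OscillabError):
    """No limit cycle detected (stable equilibrium or too-slow convergence)."""
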