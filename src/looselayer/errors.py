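"""Exception hierarchy."""


class LooseLayerError(Exception):
    """Base class for package errors."""


class ValidationError(LooseLayerError, ValueError):
    """Invalid inputs or violated type invariants."""


class StabilityError(LooseLayerError):
    """Integrator step too coarse for the requested kinetics."""


class NoDecayError(LooseLayerError):
    """Autocorrelation curve carries no resolvable decay."""


class FitError(LooseLayerError):
    """Nonlinear fit failed to converge after restarts."""
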