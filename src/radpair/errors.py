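"""Exception types for numerical failure modes."""


class NumericalAccuracyError(RuntimeError):
    """A finite-difference stencil or quadrature failed to converge.

    Carries the last two estimates so the caller can judge the residual
    disagreement.
    """

    def __init__(self, message: str, estimates: tuple[float, float] | None = None):
        super().__init__(message)
        self.estimates = estimates


class DegenerateExtremumError(RuntimeError):
    """A lifetime scan found no magnetic field response above noise
    (e.g. a system without hyperfine couplings is field-independent)."""
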