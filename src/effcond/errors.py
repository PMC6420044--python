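"""Exception types shared across the package."""


class EffcondError(Exception):
    """Base class for package-specific failures."""


class StructuralError(EffcondError, ValueError):
    """A morphology is not a rooted tree (cycle, multiple roots, orphan)."""


class SWCParseError(EffcondError, ValueError):
    """An SWC file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class SingularityError(EffcondError, ZeroDivisionError):
    """A closed-form expression was evaluated at a pole (zero denominator)."""


class NumericalInstabilityError(EffcondError, RuntimeError):
    """Integration diverged; names the time step in use."""

    def __init__(self, dt: float, t: float, vmax: float):
        super().__init__(
            f"membrane potential exceeded 500 mV (|V|={vmax:.1f}) at t={t:.2f} ms "
            f"with dt={dt} ms; reduce dt or check parameters"
        )
        self.dt = dt


class AlignmentError(EffcondError, ValueError):
    """Two trace sets that must share a time grid do not."""


class FitFailureError(EffcondError, RuntimeError):
    """Nonlinear waveform fit failed to converge after bounded restarts."""
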