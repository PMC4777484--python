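"""Exception types shared across the package."""


class FracHHError(Exception):
    """Base class for all frachh errors."""


class ConfigError(FracHHError):
    """Invalid configuration value or malformed config file."""


class InputError(FracHHError):
    """Invalid runtime input (non-finite voltage, trace too short, ...)."""


class DivergenceError(FracHHError):
    """A simulation left its stability envelope.

    Carries enough context to identify the unstable configuration: the
    fractional gate, the order ``eta``, the time step, and the first bad
    simulation time.  The documented instability of the power-law m gate at
    eta <= 0.2 surfaces through this exception rather than being clamped.
    """

    def __init__(self, message, *, gate=None, eta=None, dt=None,
                 step=None, time_ms=None):
        super().__init__(message)
        self.gate = gate
        self.eta = eta
        self.dt = dt
        self.step = step
        self.time_ms = time_ms


class NumericError(FracHHError):
    """A numerical routine could not reach its accuracy target."""


class FitError(NumericError):
    """Exponential fit failed to converge; carries the initial guesses."""

    def __init__(self, message, *, initial_guesses=None):
        super().__init__(message)
        self.initial_guesses = initial_guesses


class UndefinedWidthError(FracHHError):
    """The half-height level is not crossed on both flanks of a spike.

    Raised by :func:`frachh.spikes.half_width`; pseudo-plateau events are
    recognized partly through this failure mode.
    """
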