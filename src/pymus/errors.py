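"""Exception hierarchy shared across the simulator."""


class PymusError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PymusError, ValueError):
    """A model parameter violates its domain (non-positive conductance, ...)."""


class FeasibilityError(PymusError, ValueError):
    """A target property set admits no positive-parameter solution.

    Carries ``constraint`` (name of the first violated constraint) and
    ``residuals`` (dict of diagnostic quantities) for reporting.
    """

    def __init__(self, message, constraint=None, residuals=None):
        super().__init__(message)
        self.constraint = constraint
        self.residuals = residuals or {}


class ConfigurationError(PymusError, ValueError):
    """Unknown channel, gating variable, preset or malformed config."""


class IntegrationError(PymusError, RuntimeError):
    """ODE integration failed; carries the last good time and state."""

    def __init__(self, message, t_last=None, y_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


class SignalParseError(PymusError, ValueError):
    """A signal file could not be parsed; carries the offending row."""

    def __init__(self, message, row=None):
        super().__init__(message)
        self.row = row
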