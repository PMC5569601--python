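"""Exception types raised across the package."""


class GastrosimError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GastrosimError, ValueError):
    """An input lies outside the physical domain of a law (e.g. negative
    concentration or viscosity)."""


class DegenerateStateError(GastrosimError, ValueError):
    """A derived quantity is undefined for the given state (e.g. thickener
    concentration with zero liquid mass)."""


class ConfigurationError(GastrosimError, ValueError):
    """Inconsistent configuration, e.g. an emptying-rate hypothesis paired
    with constants it does not use."""


class StabilityError(GastrosimError, RuntimeError):
    """A numerical stability condition (CFL, reaction sub-step) is violated.

    The message always names the admissible step size.
    """


class SimulationInstabilityError(GastrosimError, RuntimeError):
    """The explicit time march produced a negative mass or NaN."""


class ParseError(GastrosimError, ValueError):
    """A delimited-text input failed validation; the message names the row."""
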