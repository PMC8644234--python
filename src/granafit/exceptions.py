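"""Exception hierarchy shared across the analysis modules."""


class GranafitError(Exception):
    """Base class for all package errors."""


class FormatError(GranafitError):
    """A file could not be parsed as the declared dialect."""


class ValidationError(GranafitError):
    """A record violates its structural invariants."""


class CoverageError(GranafitError):
    """The data do not cover a time window / wavelength required by the operation."""


class DomainError(GranafitError):
    """Inputs are outside the mathematical domain of the operation."""


class DegenerateError(GranafitError):
    """The signal carries no usable structure (flat trace, FM <= F0, ...)."""


class NonSaturatedError(GranafitError):
    """An induction curve never approaches its saturation plateau."""


class ProtocolError(GranafitError):
    """Required protocol events are missing or inconsistent."""


class FitError(GranafitError):
    """A least-squares fit returned a non-finite or unusable result."""


class NoLatticeError(GranafitError):
    """No stable 2D lattice could be identified in a point set."""
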