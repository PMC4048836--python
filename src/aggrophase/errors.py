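"""Typed exceptions shared across aggrophase modules."""


class AggrophaseError(Exception):
    """Base class for all package errors."""


class InvalidStateError(AggrophaseError):
    """A state object violates its invariants (non-finite or negative)."""


class IntegrationError(AggrophaseError):
    """The ODE solver failed to converge."""


class TruncationLeakWarning(UserWarning):
    """Mass leaking past the size-truncation boundary exceeded threshold."""


class PreconditionError(AggrophaseError):
    """An operation was called outside its stated preconditions."""


class BracketingError(AggrophaseError):
    """Bisection bracket endpoints classify to the same phase."""


class FitError(AggrophaseError):
    """A fit could not be performed (too few points, degenerate data)."""


class DegenerateFitError(FitError):
    """Data cover only one kinetic regime; names the missing regime."""


class ConfigError(AggrophaseError):
    """Malformed or invalid configuration input."""


class CapacityError(AggrophaseError):
    """Requested occupancy exceeds lattice capacity."""


class FrozenStateError(AggrophaseError):
    """No events have positive rate; the simulation cannot advance."""


class WindowError(AggrophaseError):
    """An empty or invalid analysis window."""


class BinningError(AggrophaseError):
    """Too few events for the requested histogram binning."""


class SupportError(AggrophaseError):
    """Curves have disjoint support after rescaling."""
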