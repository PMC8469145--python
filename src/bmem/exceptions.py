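"""Exception hierarchy shared across the package."""


class BmemError(Exception):
    """Base class for all package errors."""


class ParameterError(BmemError, ValueError):
    """A scalar or matrix parameter is outside its admissible range."""


class ShapeError(BmemError, ValueError):
    """An array argument has the wrong dimensions."""


class BlanketStructureError(BmemError, ValueError):
    """A model violates one of the structural invariants required for a
    Markov blanket at steady state.

    The ``invariant`` attribute names the failed check.
    """

    def __init__(self, invariant: str, message: str):
        self.invariant = invariant
        super().__init__(f"{invariant}: {message}")


class StabilityError(BmemError, RuntimeError):
    """The requested integration step is unstable for this system."""


class IntegrationError(BmemError, RuntimeError):
    """An integration step produced an invalid state (e.g. a covariance
    that lost positive-definiteness); usually resolved by a smaller dt."""


class GeneratorValidityError(BmemError, ValueError):
    """The categorical rate-matrix construction would produce negative
    off-diagonal transition rates (requires theta <= 4*gamma)."""
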