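"""Exception types shared across the derivation pipeline."""


class CortimapError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CortimapError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(CortimapError):
    """Too few measured data points to perform a fit."""


class CompletionError(CortimapError):
    """A data-completion step cannot be carried out (e.g. an architectural
    type has no measured representative)."""


class InvalidStateError(CortimapError):
    """An operation was called on inconsistent or incomplete intermediate
    state (e.g. population sizes requested before completion)."""


class FitFailureError(CortimapError):
    """A maximum-likelihood fit failed to converge from all restarts."""


class NegativeCycleError(CortimapError):
    """The path graph contains a reachable negative-distance cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"negative-distance cycle: {' -> '.join(map(str, self.cycle))}")
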