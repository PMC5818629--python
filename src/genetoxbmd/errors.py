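"""Exception hierarchy shared across the package."""


class GenetoxBmdError(Exception):
    """Base class for all package errors."""


class SchemaError(GenetoxBmdError):
    """Input table does not have the required columns/types."""


class ValidationError(GenetoxBmdError):
    """Data violate a dataset invariant (doses, counts, denominators...)."""


class ContractError(GenetoxBmdError):
    """An operation was called outside its documented precondition."""


class NoDoseDependenceError(ContractError):
    """BMD requested for a model with no dose effect (m1 or non-increasing fit)."""


class BmrUnreachableError(ContractError):
    """The benchmark response exceeds the model's asymptotic maximum.

    Carries the asymptote (as a multiple of background) in ``asymptote``.
    """

    def __init__(self, message: str, asymptote: float):
        super().__init__(message)
        self.asymptote = asymptote


class FitError(GenetoxBmdError):
    """Optimisation failed to converge from every start."""
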