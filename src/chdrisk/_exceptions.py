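"""Exception hierarchy for chdrisk."""


class ChdriskError(Exception):
    """Base class for all package errors."""


class SchemaError(ChdriskError):
    """A required column is missing or a column cannot be interpreted."""


class DomainError(ChdriskError, ValueError):
    """An input value lies outside its scientifically valid domain."""


class FitError(ChdriskError):
    """A model fit could not be completed."""


class ConvergenceError(FitError):
    """Iterative fitting failed to converge."""


class ZeroVarianceError(FitError):
    """A model term is constant in the data."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"term {term!r} has zero variance in the fitting data")
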