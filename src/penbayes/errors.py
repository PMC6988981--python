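"""Exception hierarchy shared across the package."""


class PenbayesError(ValueError):
    """Base class for all penbayes errors."""


class InputDomainError(PenbayesError):
    """An input violates its domain (negative counts, k > n, baseline outside (0,1), ...)."""


class UndefinedEstimateError(PenbayesError):
    """The penetrance estimate is mathematically undefined (0/0: no carriers in either arm)."""


class UndefinedCoefficientError(PenbayesError):
    """The coefficient of range is undefined (both interval bounds are zero)."""


class TableParseError(InputDomainError):
    """A tabular input failed validation; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
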