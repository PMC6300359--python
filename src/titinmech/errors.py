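"""Exception types shared across the package."""


class TitinmechError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TitinmechError, ValueError):
    """An input violates a documented precondition."""


class DomainError(TitinmechError, ValueError):
    """A value falls outside the mathematical domain of a model.

    Raised e.g. when a polymer extension reaches or exceeds its contour
    length, where the wormlike-chain force diverges.
    """


class FitError(TitinmechError, RuntimeError):
    """A nonlinear fit failed to converge or is non-identifiable."""


class TableFormatError(TitinmechError, ValueError):
    """A tabular input file is malformed; message names row and column."""
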