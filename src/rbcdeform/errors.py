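"""Exception hierarchy shared across the package."""


class RBCDeformError(Exception):
    """Base class for all package errors."""


class ParameterError(RBCDeformError, ValueError):
    """A parameter value violates its contract."""


class GenerationError(RBCDeformError, RuntimeError):
    """Synthetic-data generation could not complete (e.g. placement failure)."""


class InputError(RBCDeformError, ValueError):
    """Malformed or inconsistent input data."""


class EmptySummaryError(RBCDeformError, ValueError):
    """A deformability summary was requested for zero cells."""


class ZeroVarianceError(RBCDeformError, ValueError):
    """A correlation is undefined because one variable is constant."""
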