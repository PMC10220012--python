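"""Exception hierarchy shared across limnoflux modules."""


class LimnofluxError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LimnofluxError, ValueError):
    """A numeric argument violates a stated precondition."""


class RangeError(LimnofluxError, ValueError):
    """A depth, age or time falls outside the modelled/tabulated span."""


class SchemaError(LimnofluxError, ValueError):
    """A table is missing a required column or references an unknown variable."""


class DataError(LimnofluxError, ValueError):
    """Input rows are internally inconsistent (reversals, missing cells, ...)."""


class CalibrationError(RangeError):
    """A radiocarbon age cannot be placed on the calibration curve."""


class InsufficientDataError(DataError):
    """Series too short for the requested statistical procedure."""


class ConvergenceError(LimnofluxError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class CoverageError(DataError):
    """A binned time grid is too sparsely populated to analyse."""
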