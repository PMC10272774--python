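"""Exception hierarchy.

The CLI maps these onto distinct exit codes so batch callers can tell
bad arguments from bad data from convergence problems.
"""


class SynergyKitError(Exception):
    """Base class for all synergykit errors."""


class ArgumentError(SynergyKitError, ValueError):
    """Invalid argument values or incompatible shapes."""


class DataError(SynergyKitError, ValueError):
    """Input data violates a contract (non-finite, negative, constant...)."""


class ConvergenceError(SynergyKitError, RuntimeError):
    """An iterative solver failed to produce a usable result."""


class DegeneracyError(SynergyKitError, RuntimeError):
    """The requested factorization rank exceeds the number of
    distinguishable pure variables in the data."""


class NotStaticError(DataError):
    """A segment assumed static (for gravity calibration) is not."""


class CalibrationError(SynergyKitError, RuntimeError):
    """Gravity reference missing or non-positive."""


class UndefinedMetricError(DataError):
    """A metric (CC, VAF) is undefined for the given input, e.g. a
    constant series has no variance to correlate."""
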