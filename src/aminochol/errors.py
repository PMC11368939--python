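"""Exception hierarchy shared across the package."""


class AminocholError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(AminocholError):
    """A measurement file violates the documented CSV dialect."""


class MissingBaselineError(TableFormatError):
    """A (system, temperature) group has no zero-molality solvent row."""


class DuplicateRecordError(TableFormatError):
    """Two records share the same (system, temperature, molality) key."""


class DomainError(AminocholError, ValueError):
    """An argument is outside the physical domain of an operation."""


class FitError(AminocholError):
    """A least-squares fit cannot be performed (too few or degenerate points)."""


class ConfigurationError(AminocholError):
    """Required parameters or species entries are missing."""


class ConvergenceError(AminocholError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class NoSolutionError(AminocholError):
    """The density solver found no root in the physical packing range."""


class StateError(AminocholError):
    """A thermodynamic state is unphysical (e.g. packing fraction too high)."""
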