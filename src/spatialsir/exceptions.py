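"""Exception types shared across the package."""


class SpatialSIRError(Exception):
    """Base class for all package errors."""


class ParameterError(SpatialSIRError, ValueError):
    """A structural or epidemic parameter violates a model constraint."""


class InfeasibleError(SpatialSIRError, ValueError):
    """A requested control target cannot be reached for any admissible
    value of the free parameter (e.g. no intra-degree K can lift the
    lattice threshold above the given infection probability)."""


class ConsistencyError(SpatialSIRError, RuntimeError):
    """An internal analytic identity failed (the two thresholds came out
    in the wrong order, a root left its bracket, ...)."""


class SchedulingError(SpatialSIRError, ValueError):
    """An intervention schedule is unsorted, overlapping or otherwise
    impossible to execute."""


class ConfigError(SpatialSIRError, ValueError):
    """A run configuration failed validation."""
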