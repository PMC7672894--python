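"""Exception hierarchy for vafmix.

Errors are split by failure class so the CLI can map them to exit
diagnostics: configuration (bad arguments / missing columns), validation
(data violates a documented contract), fit (numerical failure of the
mixture fit) and simulation (branching process could not be realised).
"""


class VafmixError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VafmixError):
    """A required column, sample, field or option is missing or malformed."""


class ValidationError(VafmixError):
    """Input data violate a documented invariant (e.g. frequency outside [0, 1])."""


class FitError(VafmixError):
    """The mixture fit (or every restart of it) failed or degenerated."""


class DegenerateClusterError(FitError):
    """A component collapsed: weighted variance >= m(1-m) or vanishing weight."""


class DegenerateTailError(FitError):
    """Pareto tail cannot be estimated (all mass at the scale point)."""


class SimulationError(VafmixError):
    """The branching-process simulation repeatedly went extinct or is invalid."""
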