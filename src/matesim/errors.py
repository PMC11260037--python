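"""Exception hierarchy for matesim."""


class MateSimError(Exception):
    """Base class for all matesim errors."""


class ConfigurationError(MateSimError, ValueError):
    """Invalid user-supplied configuration (counts, rates, design tags...)."""


class SimulationError(MateSimError, RuntimeError):
    """The simulation cannot proceed (e.g. a sex ran out of candidates)."""


class DegenerateTraitError(SimulationError):
    """All QTL are fixed in the scaling population: the trait has no variance.

    Callers are expected to resample QTL positions/effects and retry.
    """


class PedigreeError(MateSimError, ValueError):
    """Malformed pedigree (parent after offspring, cycle, unknown id)."""


class UndefinedStatisticError(MateSimError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
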