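"""Exception hierarchy shared across the pipeline."""


class AntiradicalError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AntiradicalError):
    """A tabular input does not conform to its declared dialect."""


class DuplicateRecordError(FormatError):
    """The same (compound_id, charge_state, phase) key appears twice."""


class DegenerateHardnessError(AntiradicalError):
    """I <= A: the hardness is non-positive and S, omega are undefined."""

    def __init__(self, ionization_potential: float, electron_affinity: float,
                 compound_id: str = ""):
        self.ionization_potential = ionization_potential
        self.electron_affinity = electron_affinity
        self.compound_id = compound_id
        who = f" for {compound_id!r}" if compound_id else ""
        super().__init__(
            f"degenerate hardness{who}: I={ionization_potential} <= "
            f"A={electron_affinity}"
        )


class ConfigurationError(AntiradicalError):
    """A configuration value is unusable (e.g. zero reference power)."""


class ConventionMismatchError(AntiradicalError):
    """Descriptor rows with different conventions in one table."""


class ExtrapolationError(AntiradicalError):
    """The 50% level lies outside the observed dose-response range."""


class FitError(AntiradicalError):
    """A dose-response fit is degenerate or failed to converge."""


class GenerationError(AntiradicalError):
    """A synthetic-data specification violates its preconditions."""
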