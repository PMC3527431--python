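"""Exception hierarchy for grnevo.

Exit-code mapping used by the CLI: configuration problems (:class:`ConfigError`)
exit with 2, mutational meltdown (:class:`MeltdownError`) with 3, any other
:class:`GrnError` with 1.
"""


class GrnError(Exception):
    """Base class for all grnevo errors."""


class ConfigError(GrnError):
    """A configuration document or parameter set is invalid."""


class GenerationFailureError(GrnError):
    """Rejection sampling of a developmentally stable network exhausted its tries."""

    def __init__(self, attempts: int):
        self.attempts = attempts
        super().__init__(
            f"no developmentally stable network found in {attempts} attempts"
        )


class MeltdownError(GrnError):
    """The offspring pool could not be filled with viable genotypes.

    Raised when the number of development attempts exceeds the configured cap,
    converting a silent hang under lethal mutation pressure into a diagnosable
    failure. ``generation`` is the generation at which filling failed.
    """

    def __init__(self, generation: int, attempts: int):
        self.generation = generation
        self.attempts = attempts
        super().__init__(
            f"offspring pool not filled after {attempts} attempts "
            f"at generation {generation}"
        )


class FitDegenerateError(GrnError):
    """Too few usable points remain for a power-law fit."""
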