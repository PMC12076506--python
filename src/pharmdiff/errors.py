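"""Exception hierarchy shared across pharmdiff modules."""


class PharmdiffError(Exception):
    """Base class for all pharmdiff errors."""


class FormatError(PharmdiffError):
    """Input file could not be parsed as the expected chemical format."""


class EmptyContextError(PharmdiffError):
    """No protein atoms remained after filtering."""


class CapacityError(PharmdiffError):
    """More pharmacophore points than available atom slots."""


class ConfigError(PharmdiffError):
    """Invalid configuration value (unknown family, bad vocabulary, lambda < 0, ...)."""


class SchemaError(PharmdiffError):
    """A JSON document did not validate against its schema."""


class UndefinedMetricError(PharmdiffError):
    """The metric is undefined for this input (e.g. reference forms no H-bonds)."""


class GenerationError(PharmdiffError):
    """Fixture or sample generation failed (infeasible geometry, denoiser failure)."""


class StepError(PharmdiffError):
    """Diffusion step index outside the schedule range."""
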