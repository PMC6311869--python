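"""Exception hierarchy shared across the package."""


class ImmunoflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ImmunoflowError):
    """Invalid cohort, panel, population, or tree configuration."""


class GatingError(ImmunoflowError):
    """Gating could not be applied to an event table."""


class InferenceError(ImmunoflowError):
    """A statistical comparison was requested with insufficient data."""


class UndefinedScoreError(ImmunoflowError):
    """A ratio score was requested with a zero denominator."""


class PipelineError(ImmunoflowError):
    """A pipeline stage failed; the message names the stage and subject."""
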