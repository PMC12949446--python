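"""Exception hierarchy shared across the package."""


class SepsisValError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SepsisValError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(SepsisValError):
    """A cohort table on disk does not match the documented schema."""


class UndefinedMetricError(SepsisValError):
    """A metric is undefined on the given input (e.g. single-class AUROC)."""


class PipelineError(SepsisValError):
    """A pipeline stage failed; the message names the stage."""
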