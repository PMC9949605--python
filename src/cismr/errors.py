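"""Exception hierarchy.

All package-specific failures derive from :class:`CismrError` so callers can
catch one base class; the CLI maps subclasses onto exit codes.
"""


class CismrError(Exception):
    """Base class for all cismr errors."""


class SumstatsError(CismrError):
    """Malformed or invariant-violating summary-statistics input."""


class LdError(CismrError):
    """Invalid LD matrix, or a variant missing from it."""


class HarmonizationError(CismrError):
    """Exposure and outcome tables cannot be harmonized."""


class EstimationError(CismrError):
    """Numerical failure inside a causal estimator."""


class ConfigError(CismrError):
    """Invalid analysis or simulation configuration."""


class PipelineError(CismrError):
    """Pipeline-level failure, e.g. no instruments survive selection."""
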