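"""Exception hierarchy used across the package.

All errors derive from :class:`EnrichClustError` so callers can catch the
package's failures with a single ``except`` clause; the subclasses separate
user-input problems from configuration mistakes and internal inconsistencies.
"""


class EnrichClustError(Exception):
    """Base class for all errors raised by enrichclust."""


class ConfigurationError(EnrichClustError):
    """A parameter or configuration value is invalid (e.g. top_n < 1)."""


class InputError(EnrichClustError):
    """User-supplied data is unusable (empty file, missing log2FC, ...)."""


class FormatError(EnrichClustError):
    """A file does not conform to its declared format (GMT, reply text)."""


class DomainError(EnrichClustError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ConsistencyError(EnrichClustError):
    """Two data structures that must agree do not (e.g. a hit's term is
    missing from the cluster assignment)."""


class PipelineError(EnrichClustError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
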