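"""Exception hierarchy.

Every error the library raises deliberately derives from
:class:`SrnaSignatureError`, so callers (and the CLI) can distinguish
domain errors from bugs.
"""


class SrnaSignatureError(Exception):
    """Base class for all errors raised by this package."""


class CoordinateError(SrnaSignatureError):
    """A region or motif does not fit on the reference."""


class ConflictError(SrnaSignatureError):
    """Two embedded motifs overlap."""


class DesignError(SrnaSignatureError):
    """An experiment design is inconsistent with its condition semantics."""


class ConfigError(SrnaSignatureError):
    """A configuration value fails validation."""


class InsufficientDataError(SrnaSignatureError):
    """Too few observations for the requested statistic."""


class NormalizationError(SrnaSignatureError):
    """A normalization denominator is zero or unavailable."""


class StageError(SrnaSignatureError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
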