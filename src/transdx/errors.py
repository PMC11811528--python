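"""Exception hierarchy for transdx.

All package-specific failures derive from :class:`TransdxError` so callers
can catch one base class at pipeline boundaries.
"""


class TransdxError(Exception):
    """Base class for all transdx errors."""


class ConfigError(TransdxError):
    """Invalid configuration (dimensions, probabilities, coupling matrix...)."""


class FormatError(TransdxError):
    """Malformed on-disk cohort data (ragged rows, unknown IDs, bad codes)."""


class CodeParseError(FormatError):
    """An ICD-10 code string could not be parsed."""


class MatchingInfeasibleError(TransdxError):
    """The control pool cannot supply a required sex stratum."""


class StageError(TransdxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
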