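"""Exception hierarchy for the preprocessing pipeline."""


class NmrPrepError(Exception):
    """Base class for all package-specific errors."""


class EmptyCohortError(NmrPrepError):
    """Raised when a Bruker root directory contains no acquisitions."""


class BrukerFormatError(NmrPrepError):
    """Raised when an ``acqus``/``fid`` pair cannot be decoded."""


class StageError(NmrPrepError):
    """Raised when a preprocessing stage receives invalid input."""


class ConfigError(NmrPrepError):
    """Raised for pipeline configuration schema violations."""
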