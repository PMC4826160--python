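"""Exception hierarchy for the ctc-origin pipeline.

Configuration problems (bad tables, invalid scene parameters, sex/panel
mismatches) are distinguished from runtime failures so the command-line
layer can map them to distinct exit codes (2 vs 1).
"""


class CTCOriginError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CTCOriginError):
    """Invalid user-supplied configuration: tables, parameters, panels."""


class DataIntegrityError(CTCOriginError):
    """An input table is structurally inconsistent (e.g. a missing channel
    measurement for a segmented object)."""


class GenerationError(CTCOriginError):
    """Synthetic scene generation could not satisfy its constraints."""


class UndefinedFractionError(CTCOriginError, ZeroDivisionError):
    """A percentage was requested with a zero denominator."""


class UndefinedRatioError(CTCOriginError, ZeroDivisionError):
    """A fold ratio was requested against a zero or negative denominator."""
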