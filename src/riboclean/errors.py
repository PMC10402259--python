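"""Exception hierarchy for riboclean.

All package-specific failures derive from :class:`RibocleanError` so callers
can catch one base class at pipeline boundaries.
"""


class RibocleanError(Exception):
    """Base class for all riboclean errors."""


class ConfigError(RibocleanError):
    """Invalid configuration (simulation or run config)."""


class ParseError(RibocleanError):
    """A file could not be parsed (malformed TSV/GMT/YAML)."""


class StructuralError(RibocleanError):
    """Inputs parsed but are mutually inconsistent (e.g. metadata/count mismatch)."""


class DesignError(RibocleanError):
    """A model design matrix is unusable (rank deficiency, missing groups)."""


class NormalizationError(RibocleanError):
    """Size factors cannot be computed from the given counts."""


class ContractError(RibocleanError):
    """An operation was called with arguments violating its contract."""
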