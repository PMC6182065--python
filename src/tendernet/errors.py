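"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError (and subclasses) to exit code 3.
"""


class TenderNetError(Exception):
    """Base class for all package errors."""


class ConfigError(TenderNetError):
    """Invalid configuration or parameter value."""


class DataError(TenderNetError):
    """Invalid or inconsistent input data."""


class PedigreeError(DataError):
    """Pedigree structure problem (cycle, duplicate ID, bad parent)."""


class DesignError(DataError):
    """Design matrix problem (rank deficiency, dimension mismatch)."""


class SelectionError(DataError):
    """Extreme-group selection cannot be satisfied."""


class NormalizationError(DataError):
    """Library-size normalization cannot be computed."""
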