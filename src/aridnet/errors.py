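"""Typed exceptions used across the package."""


class AridnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AridnetError):
    """An invalid parameter or simulation design field."""


class DatasetError(AridnetError):
    """A malformed or inconsistent input dataset (file, table, tree)."""


class ConstantInputError(AridnetError):
    """A statistic is undefined because an input vector is constant."""
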