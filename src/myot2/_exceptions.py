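"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class Myot2Error(Exception):
    """Base class for all package errors."""


class InvalidParameterError(Myot2Error, ValueError):
    """A parameter violates its documented constraints."""


class ConfigError(Myot2Error):
    """A pipeline configuration is inconsistent or incomplete."""


class DataError(Myot2Error):
    """An input file or array is malformed or misaligned."""


class NumericalError(Myot2Error):
    """A computation failed in a way that invalidates the whole result."""
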