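"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class XdevoError(Exception):
    """Base class for all package errors."""


class ConfigError(XdevoError, ValueError):
    """A run configuration or parameter is invalid."""


class DataError(XdevoError, ValueError):
    """Input data violate a contract (shape, scale, missing values...)."""
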