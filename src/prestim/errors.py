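"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to exit code 2 in the CLI, ``DataError`` to exit code 3.
"""


class PrestimError(Exception):
    """Base class for all package errors."""


class ConfigError(PrestimError):
    """Invalid configuration (bad parameter values, inconsistent windows)."""


class DataError(PrestimError):
    """Invalid or degenerate data (malformed files, empty classes, zero variance)."""
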