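"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class VpptBenchError(Exception):
    """Base class for all package errors."""


class ConfigError(VpptBenchError):
    """Invalid configuration: bad thresholds, missing paths, malformed registry."""


class DataError(VpptBenchError):
    """Malformed or inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed (missing column, bad header, bad record)."""


class NotAnSnvError(DataError):
    """Alleles describe something other than a single-nucleotide substitution."""
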