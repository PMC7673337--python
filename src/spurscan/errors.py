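"""Exception hierarchy.

``InputError`` maps to exit code 1 (bad data), ``ConfigError`` to exit
code 2 (bad invocation) in the command-line layer.
"""


class SpurscanError(Exception):
    """Base class for all package errors."""


class InputError(SpurscanError):
    """Malformed or inconsistent input data (bad FASTA record, duplicate
    accession, out-of-range coordinate...)."""


class ConfigError(SpurscanError):
    """Invalid configuration (inverted ranges, missing catalogs...)."""
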