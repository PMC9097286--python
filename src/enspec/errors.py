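"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/format -> 1, fit failures -> 2,
I/O problems -> 3.
"""


class EnspecError(Exception):
    """Base class for all package errors."""


class FormatError(EnspecError):
    """Malformed input file (bad columns, duplicate keys, empty table)."""


class ValidationError(EnspecError):
    """Structurally valid input violating a domain invariant."""


class ConfigError(EnspecError):
    """Inconsistent or out-of-range configuration."""


class FitError(EnspecError):
    """Mixture fitting failed for every attempted candidate/restart."""
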