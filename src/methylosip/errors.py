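"""Exception hierarchy mapped to CLI exit codes.

Validation problems (malformed tables, bad enum values, range violations)
exit with 2, cross-reference/pairing problems with 3, numerical failures
(non-convergent fits, degenerate regressions) with 4.
"""


class MethylosipError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(MethylosipError):
    """Malformed or inconsistent input data or configuration."""

    exit_code = 2


class ConfigError(ValidationError):
    """Invalid pipeline configuration (overlapping windows, bad ranges)."""


class PairingError(MethylosipError):
    """Cross-reference failure: orphan gradients, missing metadata."""

    exit_code = 3


class NumericalError(MethylosipError):
    """Numerical failure: degenerate regression, non-convergent fit."""

    exit_code = 4
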