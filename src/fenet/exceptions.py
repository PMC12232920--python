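"""Exception hierarchy shared across the package.

The CLI maps these onto stable exit codes: :class:`DataError` (malformed or
inconsistent input) exits 3 and :class:`ConvergenceError` (numerical
non-convergence) exits 4.
"""


class FenetError(Exception):
    """Base class for all package errors."""


class DataError(FenetError):
    """Malformed, inconsistent, or missing input data."""


class InsufficientDataError(DataError):
    """Too few (equilibrated, decorrelated) samples to proceed."""


class ConvergenceError(FenetError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message, last_state=None, residual=None):
        super().__init__(message)
        self.last_state = last_state
        self.residual = residual
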