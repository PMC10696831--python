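"""Exception hierarchy.

Errors are split into three families so that callers (and the CLI exit
codes) can distinguish bad inputs from missing capabilities from runtime
failures of an otherwise valid computation.
"""


class MethnormError(Exception):
    """Base class for all package errors."""


class ValidationError(MethnormError, ValueError):
    """Input violates a documented precondition or invariant."""


class CapabilityError(MethnormError):
    """The requested operation needs data the input does not carry
    (e.g. out-of-band intensities for Noob)."""


class ConvergenceError(MethnormError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, *, n_iter: int | None = None,
                 loglik_trace: list | None = None):
        super().__init__(message)
        self.n_iter = n_iter
        self.loglik_trace = loglik_trace or []
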