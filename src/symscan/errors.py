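"""Exception hierarchy.

Separate classes exist so the command line can map failure kinds to
distinct exit codes (I/O vs precondition vs convergence).
"""


class SymscanError(Exception):
    """Base class for all package errors."""


class InputError(SymscanError):
    """A structure file or selection that cannot yield a usable trace."""


class PreconditionError(SymscanError):
    """An operation was called with arguments violating its contract."""


class ConvergenceError(SymscanError):
    """A numerical fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
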