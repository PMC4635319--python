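"""Exceptions shared across the package.

``InputError`` maps to CLI exit code 2, ``ConvergenceError`` to 3.
"""


class InputError(ValueError):
    """Malformed or out-of-domain user input (files, arguments, config)."""


class DomainError(InputError):
    """A numeric argument outside the physical domain of an operation."""


class ConvergenceError(RuntimeError):
    """An iterative solver or fitter failed to converge; carries diagnostics."""

    def __init__(self, message: str, state: dict | None = None):
        super().__init__(message)
        self.state = state or {}
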