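"""Exception types shared across the package."""

__all__ = ["InvalidInputError", "MissingDataError", "ConvergenceError"]


class InvalidInputError(ValueError):
    """An input violates a documented precondition."""


class MissingDataError(ValueError):
    """A required field or component is absent; the message names it."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed; the message carries diagnostics."""
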