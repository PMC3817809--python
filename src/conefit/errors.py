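"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file or matrix violates the expected layout (shape, header, dtype)."""


class ConvergenceError(RuntimeError):
    """An iterative solver stopped before reaching its tolerance."""
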