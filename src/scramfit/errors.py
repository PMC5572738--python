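"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates its documented domain (e.g. non-positive radius)."""


class FitConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge; carries initialization diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
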