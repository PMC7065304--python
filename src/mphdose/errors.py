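"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input data or configuration violates a documented contract."""


class DomainError(ValueError):
    """A quantity is outside its mathematical domain (e.g. dose <= 0)."""


class ConvergenceError(RuntimeError):
    """An iterative solver exhausted its iteration budget."""
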