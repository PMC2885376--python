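"""Exception types shared across the package."""


class MiractError(Exception):
    """Base class for all package errors."""


class ValidationError(MiractError, ValueError):
    """An input table, record stream or configuration violates an invariant."""
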