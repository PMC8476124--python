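class DerepressError(Exception):
    """Base class for all errors raised by this package."""


class InputError(DerepressError):
    """Invalid or inconsistent user-supplied input (CLI exit code 1)."""
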