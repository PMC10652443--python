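"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input value or file violates a documented contract.

    CLI entry points translate this into exit status 2.
    """
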