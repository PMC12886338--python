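"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violated a documented precondition."""


class FormatError(ValueError):
    """A file on disk is missing a required member or is malformed."""
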