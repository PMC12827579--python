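"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented contract (bad shapes, labels, thresholds)."""


class FormatError(ValidationError):
    """A file parsed, but its content violates the expected layout."""
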