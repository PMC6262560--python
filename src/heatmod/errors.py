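"""Exception types shared across the pipeline."""


class IngestError(ValueError):
    """Raised when an input file violates its format or an invariant."""


class ValidationError(ValueError):
    """Raised when an in-memory object or configuration is inconsistent."""
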