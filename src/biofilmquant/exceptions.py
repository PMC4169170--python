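"""Exception hierarchy for input validation failures."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class GeometryError(ValidationError):
    """Line or ROI geometry falls outside the image."""


class FormatError(ValidationError):
    """Image or table has an unsupported layout (e.g. channel count)."""


class SchemaError(ValidationError):
    """Tabular input violates the phenotype-panel schema."""
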