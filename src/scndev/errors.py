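"""Exception types shared across the pipeline."""


class InvalidConfigError(ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(ValueError):
    """Input data violate a precondition of an operation."""


class SchemaError(InvalidInputError):
    """A table is missing required columns or contains malformed values."""


class DimensionError(InvalidInputError):
    """Mismatched dimensions between data structures (e.g. table vs parcellation)."""
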