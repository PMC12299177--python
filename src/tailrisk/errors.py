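"""Exception hierarchy shared across the package."""


class TailriskError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TailriskError, ValueError):
    """A physical parameter or data value violates its contract."""


class FormatError(ValidationError):
    """An input file does not match the expected layout."""


class SchemaError(ValidationError):
    """A scenario configuration fails schema validation."""


class GridError(TailriskError, ValueError):
    """A finite-difference grid violates its stability/accuracy criteria."""
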