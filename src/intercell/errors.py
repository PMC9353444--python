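"""Exception hierarchy shared across the package."""


class IntercellError(Exception):
    """Base class for all intercell errors."""


class SchemaError(IntercellError):
    """An input table does not have the documented columns/structure."""


class ValidationError(IntercellError):
    """A value violates a documented constraint (closed vocabulary, range...)."""
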