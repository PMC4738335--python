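"""Exception hierarchy shared by all pipeline stages."""


class MukcolocError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(MukcolocError):
    """A simulation spec or run configuration is invalid; message names the field."""


class MissingInputError(MukcolocError):
    """A required input file or column is absent."""


class SchemaError(MukcolocError):
    """An input table does not match the expected schema."""


class ParseError(MukcolocError):
    """A text input could not be parsed; message includes the line number."""


class EmptyResultError(MukcolocError):
    """An analysis had zero usable observations (e.g. no cell with foci in both channels)."""


class UndefinedFoldError(MukcolocError):
    """A fold difference is undefined (test-series slope is zero or negative)."""
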