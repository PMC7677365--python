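"""Exception hierarchy shared across the package."""


class HelixCurateError(Exception):
    """Base class for all package errors."""


class StarParseError(HelixCurateError):
    """Malformed STAR content; carries the offending row index when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class FormatError(HelixCurateError):
    """A structure file could not be parsed in any supported format."""


class MissingColumnError(HelixCurateError):
    """A required metadata column is absent."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"required column missing: {column}")


class DuplicateRecordError(HelixCurateError):
    """Two particles share coordinates within one helical tube."""


class ConfigurationError(HelixCurateError):
    """Invalid parameter or missing configuration (e.g. unknown pixel size)."""


class SelectionError(HelixCurateError):
    """An atom selection resolved to nothing or to mismatched sets."""


class GeometryError(HelixCurateError):
    """Degenerate geometry (too few atoms for a plane fit, collinear sets...)."""


class RadiusError(HelixCurateError):
    """No van der Waals radius known for an element."""

    def __init__(self, element: str):
        self.element = element
        super().__init__(f"no van der Waals radius for element {element!r}")


class EmptyInputError(HelixCurateError):
    """An operation received no usable input (e.g. zero valid steps)."""


class BranchError(HelixCurateError):
    """Angular data too dispersed to average on a single branch."""
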