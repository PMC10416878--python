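"""Exception hierarchy shared across the package."""


class EpilayerError(Exception):
    """Base class for all package errors."""


class FormatError(EpilayerError):
    """An input file violates the expected schema (bad column, bad label value)."""


class RowError(FormatError):
    """A single table row is unparseable; carries the offending row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class ParameterError(EpilayerError, ValueError):
    """A parameter is outside its documented domain."""


class GraphError(EpilayerError):
    """The neighbor graph cannot be built (too few points, collinear input)."""


class PeelingError(EpilayerError):
    """The peeling wave-front cannot be seeded or targeted."""
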