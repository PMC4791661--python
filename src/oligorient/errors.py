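"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (incl. parse
and structure problems) -> 3, GeometryError -> 4.
"""


class OligorientError(Exception):
    """Base class for all package errors."""


class ConfigError(OligorientError):
    """Invalid configuration, unknown keys, or unusable parameter values."""


class DataError(OligorientError):
    """Inconsistent or missing data (observable tables, ensembles)."""


class ParseError(DataError):
    """Malformed input file."""


class StructureError(DataError):
    """Structurally inconsistent ensemble (chains/models disagree)."""


class GeometryError(OligorientError):
    """Degenerate or impossible geometry (collinear atoms, clashes)."""
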