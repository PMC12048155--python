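"""Exception hierarchy for resdenoise."""


class ResdenoiseError(Exception):
    """Base class for all package errors."""


class ParseError(ResdenoiseError):
    """Malformed or empty input that cannot be parsed."""


class ChainNotFoundError(ParseError):
    """Requested chain is absent from the structure."""


class GeometryError(ResdenoiseError):
    """Degenerate atomic geometry (collinear / coincident points)."""


class GraphError(ResdenoiseError):
    """Residue graph cannot be built from the given structure."""


class ConfigError(ResdenoiseError):
    """Invalid configuration value."""


class ShapeError(ResdenoiseError):
    """Array dimensions inconsistent with the model contract."""


class ValidationError(ResdenoiseError):
    """Input fails a semantic check (e.g. wild-type letter mismatch)."""
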