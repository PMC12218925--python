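"""Exception types shared across the package."""


class CytoHGNNError(Exception):
    """Base class for package errors."""


class InvalidConfigError(CytoHGNNError, ValueError):
    """A configuration value is outside its admissible range."""


class ShapeError(CytoHGNNError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class DegenerateInputError(CytoHGNNError, ValueError):
    """Input is structurally degenerate (empty batch, single class, isolated vertex)."""


class FormatError(CytoHGNNError, ValueError):
    """A file does not conform to the expected on-disk format."""
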