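"""Exception hierarchy."""


class FluidCamError(Exception):
    """Base class for package errors."""


class ParameterError(FluidCamError, ValueError):
    """Invalid parameter value."""


class ConfigError(FluidCamError, ValueError):
    """Invalid model or pipeline configuration."""


class ShapeError(FluidCamError, ValueError):
    """Array shape mismatch."""


class InputError(FluidCamError, ValueError):
    """Invalid operation input (counts, bounds, ...)."""


class DataError(FluidCamError, ValueError):
    """Invalid or empty dataset."""


class GenerationError(FluidCamError, ValueError):
    """Phantom generation cannot satisfy the requested geometry."""


class FormatError(FluidCamError, ValueError):
    """File content violates the expected format (bit depth, shapes, ...)."""


class CapabilityError(FluidCamError, TypeError):
    """Model does not expose what the operation requires."""


class UndefinedMetricError(FluidCamError, ValueError):
    """Requested metric has a zero denominator."""
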