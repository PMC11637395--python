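"""Exception hierarchy for the eggpale pipeline.

Every stage raises a subclass of :class:`EggpaleError`, so the CLI can map any
pipeline failure to a non-zero exit status with the stage name attached.
"""


class EggpaleError(Exception):
    """Base class for all eggpale errors."""


class InputError(EggpaleError):
    """Malformed or incompatible input data (shape/size/finiteness)."""


class ParameterError(EggpaleError):
    """A user-supplied parameter is outside its valid domain."""


class NumericalError(EggpaleError):
    """Non-finite values appeared during computation."""


class InvertibilityError(EggpaleError):
    """A 1x1 convolution weight is numerically singular."""


class DegeneracyError(EggpaleError):
    """A degenerate configuration (e.g. rank >= latent dimension)."""


class ConfigurationError(EggpaleError):
    """Incompatible artifacts (e.g. model/basis hash mismatch)."""


class PlacementError(EggpaleError):
    """A synthetic nodule was requested outside the lung field."""
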