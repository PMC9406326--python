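"""Exception hierarchy for cvfair."""


class CVFairError(Exception):
    """Base class for all cvfair errors."""


class DegenerateInputError(CVFairError, ValueError):
    """Raised for inputs with no usable variation (constant image, all-zero counts)."""


class GeometryError(CVFairError, ValueError):
    """Raised when tensor/kernel/window shapes are incompatible."""


class ConfigurationError(CVFairError, ValueError):
    """Raised for invalid architecture or training configuration."""


class InvalidProfileError(CVFairError, ValueError):
    """Raised for invalid synthetic dataset profiles."""


class StratificationError(CVFairError, ValueError):
    """Raised when a class is too small to stratify into the requested folds."""


class TrainingError(CVFairError, RuntimeError):
    """Raised when training encounters non-finite losses or gradients."""
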