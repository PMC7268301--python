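"""Exception hierarchy shared across the package."""


class WoodNIRError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(WoodNIRError, ValueError):
    """A spectral or metadata file violates the expected on-disk layout."""


class ValidationError(WoodNIRError, ValueError):
    """An in-memory object violates one of its invariants."""


class ConfigError(WoodNIRError, ValueError):
    """A configuration value is out of its admissible range."""


class DegenerateSpectrumError(WoodNIRError, ValueError):
    """A spectrum has zero spread and cannot be scatter-corrected."""


class DegenerateModelError(WoodNIRError, ValueError):
    """A fitted model carries no usable regression direction."""


class EmptySelectionError(WoodNIRError, ValueError):
    """Variable selection returned no wavenumbers; consider relaxing alpha."""
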