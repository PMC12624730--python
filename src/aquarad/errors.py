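"""Exception hierarchy.

All package errors derive from :class:`AquaradError` so callers can catch the
whole family; each subclass also derives from ``ValueError`` to behave sanely
in generic numeric code.
"""


class AquaradError(Exception):
    """Base class for all aquarad errors."""


class UnitError(AquaradError, ValueError):
    """Operation mixed spectra with incompatible physical units."""


class GridRangeError(AquaradError, ValueError):
    """Requested wavelengths fall outside the support of a spectrum."""


class GridMismatchError(AquaradError, ValueError):
    """Two objects expected on the same wavelength grid are not."""


class DegenerateInputError(AquaradError, ValueError):
    """Too few usable (unmasked, finite) samples to perform the operation."""


class ConfigurationError(AquaradError, ValueError):
    """Invalid instrument or run configuration."""


class EmptyFitError(AquaradError, ValueError):
    """A calibration fit had no usable wavelength at all."""
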