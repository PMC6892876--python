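"""Exception hierarchy shared across the package."""


class HabrushError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HabrushError, ValueError):
    """A physical quantity is outside its valid domain (e.g. non-positive mass)."""


class InvalidSpecError(HabrushError, ValueError):
    """A generator or analysis specification is internally inconsistent."""


class GeometryError(HabrushError, ValueError):
    """Requested scene does not fit the voxel grid (clipped sphere, short stack)."""


class ProfileError(HabrushError, ValueError):
    """A 1-D intensity profile is too short or otherwise unusable."""


class DegenerateHistogramError(HabrushError, ValueError):
    """Thresholding requested on a (near-)constant image."""


class DegenerateNoiseError(HabrushError, ValueError):
    """Event detection requested with zero estimated noise on a non-constant trace."""


class CalibrationError(HabrushError, ValueError):
    """ECD-to-MW calibration is underdetermined or non-monotone."""
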