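"""Exception types shared across the package."""


class SonoShadowError(Exception):
    """Base class for all package errors."""


class ValidationError(SonoShadowError, ValueError):
    """An input violates a documented precondition."""


class FrameReadError(SonoShadowError, IOError):
    """A raster file could not be read as a single grayscale frame."""


class RingUndefinedError(SonoShadowError):
    """The surrounding ring of a candidate box is empty after clipping."""


class ShadowNotEvaluableError(SonoShadowError):
    """No in-bounds rows exist below a candidate, or all profile bands
    fall outside the image, so the posterior-shadow test cannot run."""
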