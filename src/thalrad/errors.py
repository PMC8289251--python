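"""Exception hierarchy shared across the pipeline stages."""


class ThalradError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThalradError):
    """A configuration object violates its invariants."""


class DegenerateRoiError(ThalradError):
    """The region of interest is empty or too small for the requested feature."""


class ResamplingError(ThalradError):
    """Target spacing is not an integer multiple of the input spacing."""


class DecompositionError(ThalradError):
    """Grid too small for the requested wavelet filter."""


class ScreeningError(ThalradError):
    """Univariate screening received labels with fewer than two classes."""


class FoldError(ThalradError):
    """Cross-validation fold construction is impossible for the given sizes."""
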