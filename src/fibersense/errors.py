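"""Exception hierarchy shared across the package."""


class FibersenseError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FibersenseError, ValueError):
    """A configuration or function parameter is invalid."""


class GeometryError(FibersenseError, ValueError):
    """An object's geometry is inconsistent with the imaging setup."""


class InputError(FibersenseError, ValueError):
    """Input data (arrays, series, files) violate a precondition."""


class FormatError(FibersenseError, ValueError):
    """A file on disk does not match the expected on-disk layout."""
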