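"""Exception hierarchy shared across the package."""


class EqAdaptError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(EqAdaptError, ValueError):
    """Shapes of arrays/parameters are mutually inconsistent."""


class ConfigurationError(EqAdaptError, ValueError):
    """A parameter value is outside its admissible range or an unknown option."""


class ValidationError(EqAdaptError, ValueError):
    """Runtime data (inputs, targets, activities) violates a contract."""


class FormatError(EqAdaptError, ValueError):
    """An external file does not conform to its declared format."""
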