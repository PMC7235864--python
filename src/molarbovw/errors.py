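"""Exception hierarchy shared across the pipeline stages."""


class MolarBovwError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MolarBovwError):
    """Invalid configuration values (proportions, dimensions, unknown keys)."""


class ParameterError(MolarBovwError):
    """Invalid operator parameter (even kernel, non-positive sigma, ...)."""


class DimensionError(MolarBovwError):
    """Image/array shape unsuitable for the requested operation."""


class FormatError(MolarBovwError):
    """Unsupported image or file layout (channel count, manifest labels)."""


class CapabilityError(MolarBovwError):
    """A requested backend feature is unavailable in this build (e.g. SURF)."""


class CompatibilityError(MolarBovwError):
    """Artifacts produced with incompatible settings were combined."""


class CorruptionError(MolarBovwError):
    """A persisted artifact failed its integrity checks on load."""
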