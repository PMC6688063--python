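"""Exception hierarchy shared across the package."""


class SomatosiftError(Exception):
    """Base class for all package-specific errors."""


class VcfFormatError(SomatosiftError):
    """A VCF file does not match the expected dialect/layout."""


class BedFormatError(SomatosiftError):
    """A BED interval file is malformed."""


class ConfigurationError(SomatosiftError):
    """Invalid configuration: unknown dialect, bad thresholds, bad params."""


class UndefinedInputError(SomatosiftError, ValueError):
    """An operation was given input on which its result is undefined."""


class QuantificationError(SomatosiftError):
    """ddPCR quantification cannot proceed (e.g. saturated droplets)."""
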