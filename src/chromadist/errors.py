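"""Exception hierarchy for chromadist."""


class ChromadistError(Exception):
    """Base class for all chromadist errors."""


class ImageFormatError(ChromadistError):
    """Raised when a file cannot be read as an RGB PNG/JPEG image."""


class EmptyObjectError(ChromadistError):
    """Raised when background masking leaves zero object pixels."""


class ConfigurationError(ChromadistError):
    """Raised for invalid user-facing configuration (whites, metrics, weights)."""


class ChannelBoundsError(ChromadistError):
    """Raised when pixels fall outside the histogram channel bounds."""


class IncompatibleClusterSetsError(ChromadistError):
    """Raised when cluster sets cannot be compared or combined."""
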