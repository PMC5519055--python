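"""Exception hierarchy shared across the package."""


class USVError(Exception):
    """Base class for all errors raised by usvdetect."""


class AudioFormatError(USVError):
    """Input is not a readable PCM WAV file, or the audio is empty."""


class TooShortError(USVError):
    """Recording shorter than a single analysis window."""


class ConfigError(USVError, ValueError):
    """Invalid or inconsistent configuration values."""


class EstimationError(USVError):
    """A statistical estimate (noise profile, thresholds) cannot be formed."""
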