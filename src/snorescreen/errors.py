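"""Package-wide exception types."""


class SnoreScreenError(Exception):
    """Base class for all snorescreen errors."""


class ValidationError(SnoreScreenError, ValueError):
    """An input violated a documented precondition or invariant."""


class AudioIOError(SnoreScreenError, IOError):
    """An audio file could not be read or written."""
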