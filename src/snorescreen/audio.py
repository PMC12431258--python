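"""Audio container and WAV I/O.

All signals are mono float arrays with amplitudes nominally in [-1, 1].
Multi-channel WAV input is downmixed by averaging, matching a single
ambient-microphone recording geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import AudioIOError, ValidationError

__all__ = ["AudioSignal", "load_audio", "save_wav"]


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio signal: sample sequence plus sample rate in Hz."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("AudioSignal requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("AudioSignal samples must be finite")
        if int(self.sample_rate_hz) <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        object.__setattr__(self, "sample_rate_hz", int(self.sample_rate_hz))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def scaled(self, factor: float) -> "AudioSignal":
        return AudioSignal(self.samples * factor, self.sample_rate_hz)


_PCM_SCALES = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


def load_audio(path, target_rate_hz: int | None = None) -> AudioSignal:
    """Load a WAV file as a mono :class:`AudioSignal`.

    Integer PCM (16/24/32-bit) is rescaled to [-1, 1]; float WAV is taken
    as-is.  Multi-channel input is averaged to mono.  When ``target_rate_hz``
    is given the signal is resampled with a polyphase filter.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError, OSError) as exc:
        raise AudioIOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"zero-length audio in {path}")

    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALES:
        x = data.astype(np.float64) / _PCM_SCALES[data.dtype]
    else:
        x = data.astype(np.float64)

    if x.ndim == 2:
        x = x.mean(axis=1)

    if target_rate_hz is not None and int(target_rate_hz) != rate:
        target_rate_hz = int(target_rate_hz)
        g = math.gcd(target_rate_hz, rate)
        x = resample_poly(x, target_rate_hz // g, rate // g)
        rate = target_rate_hz
    return AudioSignal(x, rate)


def save_wav(path, signal: AudioSignal, subtype: str = "int16") -> None:
    """Write a signal to disk as 16-bit PCM (default) or 32-bit float WAV."""
    path = Path(path)
    x = np.clip(signal.samples, -1.0, 1.0)
    if subtype == "int16":
        data = np.round(x * (2.0**15 - 1)).astype(np.int16)
    elif subtype == "float32":
        data = x.astype(np.float32)
    else:
        raise ValidationError(f"unsupported WAV subtype: {subtype!r}")
    wavfile.write(path, signal.sample_rate_hz, data)
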