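"""Preprocessing: noise-spectrum estimation, spectral subtraction, framing.

The denoising stage subtracts an estimated average background-noise
magnitude spectrum from each analysis frame's magnitude spectrum, clamping
at zero, and reconstructs the waveform by overlap-add with the noisy phase:

    |X_hat(k, l)| = max(|Y(k, l)| - |N_hat(k)|, 0)

Framing uses 25 ms frames with a 10 ms hop and a (periodic) Hamming window
throughout the package, and the STFT used for denoising shares that same
convention with the FFT length rounded up to the next power of two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hamming as _hamming

from .audio import AudioSignal
from .errors import ValidationError

__all__ = [
    "NoiseProfile",
    "FrameSequence",
    "PreprocessConfig",
    "frame_params",
    "estimate_noise_spectrum",
    "spectral_subtract",
    "frame_signal",
    "denoise",
]


@dataclass(frozen=True)
class NoiseProfile:
    """Average background-noise magnitude spectrum over one-sided FFT bins."""

    mean_magnitude: np.ndarray
    n_fft: int
    method_tag: str  # "leading_seconds" | "lowest_energy_frames"

    def __post_init__(self) -> None:
        mag = np.asarray(self.mean_magnitude, dtype=np.float64)
        object.__setattr__(self, "mean_magnitude", mag)
        if mag.ndim != 1 or mag.size != self.n_fft // 2 + 1:
            raise ValidationError("noise profile must have n_fft//2 + 1 bins")
        if np.any(mag < 0) or not np.all(np.isfinite(mag)):
            raise ValidationError("noise profile entries must be finite and >= 0")


@dataclass(frozen=True)
class FrameSequence:
    """Windowed, overlapping frames of a signal plus their timing."""

    frames: np.ndarray  # (n_frames, N), already Hamming-windowed
    frame_length_samples: int
    hop_samples: int
    sample_rate_hz: int
    window_kind: str = "hamming"
    frame_start_times_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.frame_start_times_s is None:
            starts = (
                np.arange(self.frames.shape[0]) * self.hop_samples / self.sample_rate_hz
            )
            object.__setattr__(self, "frame_start_times_s", starts)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_len_s(self) -> float:
        return self.frame_length_samples / self.sample_rate_hz

    @property
    def hop_s(self) -> float:
        return self.hop_samples / self.sample_rate_hz


@dataclass(frozen=True)
class PreprocessConfig:
    """Framing and noise-estimation settings shared across the pipeline."""

    frame_ms: float = 25.0
    hop_ms: float = 10.0
    denoise: bool = True
    noise_method: str = "lowest_energy_frames"
    # the median-energy half of the frames estimates the stationary
    # background: the lowest decile alone underestimates it (selection
    # bias), leaving residual fluctuations after subtraction
    noise_fraction: float = 0.50
    noise_leading_s: float = 5.0  # used by the "leading_seconds" method


def frame_params(sample_rate_hz: int, frame_ms: float = 25.0, hop_ms: float = 10.0):
    """Frame length N and hop H in samples for the given rate."""
    n = int(round(sample_rate_hz * frame_ms / 1000.0))
    h = int(round(sample_rate_hz * hop_ms / 1000.0))
    if n < 1 or h < 1:
        raise ValidationError("frame and hop must be at least one sample")
    return n, h


def next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def _stft(x: np.ndarray, win: np.ndarray, hop: int, n_fft: int) -> np.ndarray:
    """Batched one-sided STFT, left-aligned frames, zero-padded tail.

    Returns (n_frames, n_fft//2 + 1) complex spectra.
    """
    n = win.size
    n_frames = max(1, -(-(max(x.size - n, 0)) // hop) + 1)
    need = (n_frames - 1) * hop + n
    if x.size < need:
        x = np.pad(x, (0, need - x.size))
    frames = sliding_window_view(x, n)[::hop][:n_frames] * win
    return np.fft.rfft(frames, n=n_fft, axis=1)


def _istft(
    spec: np.ndarray, win: np.ndarray, hop: int, n_fft: int, out_len: int
) -> np.ndarray:
    """Overlap-add inverse of :func:`_stft` with window-sum normalization.

    Exact inverse for unmodified spectra (the Hamming window is strictly
    positive, so the normalizing window sum never vanishes).
    """
    n = win.size
    n_frames = spec.shape[0]
    frames = np.fft.irfft(spec, n=n_fft, axis=1)[:, :n]
    alloc = n_frames * hop + n  # headroom so phase-strided views reshape cleanly
    y = np.zeros(alloc)
    den = np.zeros(alloc)
    for j in range(0, n, hop):
        width = min(hop, n - j)
        y[j : j + n_frames * hop].reshape(n_frames, hop)[:, :width] += frames[
            :, j : j + width
        ]
        den[j : j + n_frames * hop].reshape(n_frames, hop)[:, :width] += win[
            j : j + width
        ]
    y /= np.where(den > 0, den, 1.0)
    if y.size < out_len:
        y = np.pad(y, (0, out_len - y.size))
    return y[:out_len]


def estimate_noise_spectrum(
    signal: AudioSignal,
    n_fft: int,
    hop: int,
    config: PreprocessConfig | None = None,
    win_len: int | None = None,
) -> NoiseProfile:
    """Estimate the mean background-noise magnitude spectrum.

    Default method selects the ``noise_fraction`` lowest short-time-energy
    frames; the alternative averages over the first ``noise_leading_s``
    seconds of the recording.
    """
    config = config or PreprocessConfig()
    win_len = win_len or min(n_fft, signal.samples.size)
    if signal.samples.size <= win_len:
        raise ValidationError("signal must be longer than one analysis window")
    win = _hamming(win_len, sym=False)
    mag = np.abs(_stft(signal.samples, win, hop, n_fft))  # (frames, bins)

    if config.noise_method == "lowest_energy_frames":
        energy = np.sum(mag**2, axis=1)
        k = max(1, int(np.ceil(config.noise_fraction * energy.size)))
        idx = np.argsort(energy, kind="stable")[:k]
        profile = mag[idx].mean(axis=0)
        tag = "lowest_energy_frames"
    elif config.noise_method == "leading_seconds":
        n_frames = max(1, int(config.noise_leading_s * signal.sample_rate_hz / hop))
        profile = mag[:n_frames].mean(axis=0)
        tag = "leading_seconds"
    else:
        raise ValidationError(f"unknown noise method: {config.noise_method!r}")
    return NoiseProfile(profile, n_fft=n_fft, method_tag=tag)


def spectral_subtract(
    signal: AudioSignal,
    noise: NoiseProfile,
    n_fft: int,
    hop: int,
    win_len: int | None = None,
) -> AudioSignal:
    """Magnitude spectral subtraction with zero clamp and phase reuse.

    Per-frame magnitudes are reduced by the noise profile and clamped at
    zero; the noisy phase is reused and the waveform reconstructed by
    overlap-add.  Output length equals input length.
    """
    if noise.n_fft != n_fft:
        raise ValidationError(
            f"noise profile n_fft={noise.n_fft} does not match n_fft={n_fft}"
        )
    win_len = win_len or min(n_fft, signal.samples.size)
    win = _hamming(win_len, sym=False)
    spec = _stft(signal.samples, win, hop, n_fft)  # (frames, bins)
    mag = np.abs(spec)
    clean_mag = np.maximum(mag - noise.mean_magnitude[None, :], 0.0)
    # reuse noisy phase; avoid 0/0 where the frame magnitude is zero
    phase = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0)
    out = _istft(clean_mag * phase, win, hop, n_fft, signal.samples.size)
    return AudioSignal(out, signal.sample_rate_hz)


def denoise(signal: AudioSignal, config: PreprocessConfig | None = None) -> AudioSignal:
    """Noise-estimate + spectral-subtract using the package framing.

    Equivalent to :func:`estimate_noise_spectrum` followed by
    :func:`spectral_subtract`, sharing one STFT of the signal.
    """
    config = config or PreprocessConfig()
    n, h = frame_params(signal.sample_rate_hz, config.frame_ms, config.hop_ms)
    if signal.samples.size <= n:
        return signal
    n_fft = next_pow2(n)
    win = _hamming(n, sym=False)
    spec = _stft(signal.samples, win, h, n_fft)
    mag = np.abs(spec)
    if config.noise_method == "lowest_energy_frames":
        energy = np.sum(mag**2, axis=1)
        k = max(1, int(np.ceil(config.noise_fraction * energy.size)))
        profile = mag[np.argsort(energy, kind="stable")[:k]].mean(axis=0)
    elif config.noise_method == "leading_seconds":
        n_frames = max(1, int(config.noise_leading_s * signal.sample_rate_hz / h))
        profile = mag[:n_frames].mean(axis=0)
    else:
        raise ValidationError(f"unknown noise method: {config.noise_method!r}")
    clean_mag = np.maximum(mag - profile[None, :], 0.0)
    phase = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0)
    out = _istft(clean_mag * phase, win, h, n_fft, signal.samples.size)
    return AudioSignal(out, signal.sample_rate_hz)


def frame_signal(
    signal: AudioSignal, frame_ms: float = 25.0, hop_ms: float = 10.0
) -> FrameSequence:
    """Cut a signal into overlapping Hamming-windowed frames.

    frame i holds x(n + i*H) * w(n) for 0 <= n < N, with
    n_frames = floor((len(x) - N) / H) + 1.
    """
    n, h = frame_params(signal.sample_rate_hz, frame_ms, hop_ms)
    x = signal.samples
    if x.size < n:
        raise ValidationError(
            f"signal of {x.size} samples is shorter than one frame ({n})"
        )
    window = _hamming(n, sym=False)
    view = sliding_window_view(x, n)[::h]
    frames = view * window  # copies; the view itself stays read-only
    return FrameSequence(
        frames=frames,
        frame_length_samples=n,
        hop_samples=h,
        sample_rate_hz=signal.sample_rate_hz,
    )
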