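"""Frame-level acoustic features and Mel-spectrogram extraction.

The endpoint detector scores every 25 ms frame with four features:

* short-time energy           E_i = sum_n x_i(n)^2
* spectral entropy            H_i = -sum_k P_i(k) log(P_i(k) + eps),
                              P_i(k) = |X_i(k)|^2 / sum_k |X_i(k)|^2
* zero-crossing rate          ZCR_i = (1/2N) sum_n |sgn x_i(n) - sgn x_i(n-1)|
* spectral centroid           C_i = sum_f f |X_i(f)| / sum_f |X_i(f)|

Snoring frames show elevated energy, a compact (low-entropy) spectrum,
a smooth waveform (low ZCR) and energy concentrated at low-to-mid
frequencies (low centroid) relative to the ambient background.

The classifier consumes 128x128 log-Mel spectrograms.  Two Mel mappings
are available: the conventional HTK form m(f) = 2595 log10(1 + f/700)
(default) and a "paper" variant with denominator 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import AudioSignal
from .errors import ValidationError
from .preprocess import FrameSequence

__all__ = [
    "FrameFeatureTable",
    "MelSpectrogram",
    "MelConfig",
    "short_time_energy",
    "spectral_entropy",
    "zero_crossing_rate",
    "spectral_centroid",
    "compute_feature_table",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "mel_spectrogram",
]

DEFAULT_ENTROPY_EPS = 1e-10


@dataclass(frozen=True)
class FrameFeatureTable:
    """Per-frame (E, H, ZCR, C) values with frame timing.

    ``valid`` flags frames with non-zero content; all-zero frames take the
    conventional values H = log K (maximally uncertain) and C = 0.
    """

    energy: np.ndarray
    entropy: np.ndarray
    zcr: np.ndarray
    centroid: np.ndarray
    frame_times_s: np.ndarray
    valid: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        n = self.energy.size
        for name in ("entropy", "zcr", "centroid", "frame_times_s", "valid"):
            if getattr(self, name).size != n:
                raise ValidationError("feature table columns must share one length")

    def __len__(self) -> int:
        return self.energy.size

    def slice(self, lo: int, hi: int) -> "FrameFeatureTable":
        return FrameFeatureTable(
            self.energy[lo:hi],
            self.entropy[lo:hi],
            self.zcr[lo:hi],
            self.centroid[lo:hi],
            self.frame_times_s[lo:hi],
            self.valid[lo:hi],
            self.sample_rate_hz,
        )

    def to_frame(self):
        """Tabular view (pandas DataFrame) for TSV export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame_time_s": self.frame_times_s,
                "E": self.energy,
                "H": self.entropy,
                "ZCR": self.zcr,
                "C": self.centroid,
            }
        )


def _as_frame(frame) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 1 or frame.size == 0:
        raise ValidationError("frame must be a non-empty 1-D array")
    return frame


def short_time_energy(frame) -> float:
    """Sum of squared samples within one frame."""
    frame = _as_frame(frame)
    return float(np.sum(frame**2))


def _entropy_from_power(power: np.ndarray, eps: float) -> np.ndarray:
    """Entropy per row of a (n_frames, K) one-sided power spectrum."""
    total = power.sum(axis=1, keepdims=True)
    k = power.shape[1]
    max_h = np.log(k)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, power / np.where(total > 0, total, 1.0), 0.0)
        h = -np.sum(p * np.log(p + eps), axis=1)
    h = np.where(total[:, 0] > 0, h, max_h)  # all-zero frame: max entropy
    return np.clip(h, 0.0, max_h)


def spectral_entropy(frame, eps: float = DEFAULT_ENTROPY_EPS) -> float:
    """Shannon entropy (nats) of the frame's normalized one-sided power spectrum.

    An all-zero frame maps to the maximum-entropy value log K by convention.
    """
    frame = _as_frame(frame)
    if eps <= 0:
        raise ValidationError("eps must be positive")
    power = np.abs(np.fft.rfft(frame)) ** 2
    return float(_entropy_from_power(power[None, :], eps)[0])


def _sgn(x: np.ndarray) -> np.ndarray:
    """Sign with sgn(0) = +1 (deterministic convention)."""
    return np.where(x >= 0, 1.0, -1.0)


def zero_crossing_rate(frame) -> float:
    """Fraction of sample-to-sample sign changes, in [0, 1]."""
    frame = _as_frame(frame)
    if frame.size < 2:
        raise ValidationError("ZCR needs at least two samples")
    s = _sgn(frame)
    return float(np.sum(np.abs(s[1:] - s[:-1])) / (2.0 * frame.size))


def spectral_centroid(frame, sample_rate_hz: int) -> float:
    """Magnitude-weighted mean frequency (Hz) over the one-sided spectrum.

    Returns 0 for an all-zero frame (flagged upstream as invalid).
    """
    frame = _as_frame(frame)
    mag = np.abs(np.fft.rfft(frame))
    total = mag.sum()
    if total == 0:
        return 0.0
    freqs = np.fft.rfftfreq(frame.size, d=1.0 / sample_rate_hz)
    return float(np.sum(freqs * mag) / total)


def compute_feature_table(
    frames: FrameSequence,
    sample_rate_hz: int | None = None,
    eps: float = DEFAULT_ENTROPY_EPS,
) -> FrameFeatureTable:
    """Vectorized per-frame computation of the four detector features."""
    if frames.n_frames < 1:
        raise ValidationError("need at least one frame")
    if eps <= 0:
        raise ValidationError("eps must be positive")
    rate = sample_rate_hz or frames.sample_rate_hz
    mat = frames.frames
    energy = np.sum(mat**2, axis=1)

    spec = np.abs(np.fft.rfft(mat, axis=1))
    power = spec**2
    entropy = _entropy_from_power(power, eps)

    s = _sgn(mat)
    zcr = np.sum(np.abs(s[:, 1:] - s[:, :-1]), axis=1) / (2.0 * mat.shape[1])
    # an all-zero frame has constant sign under sgn(0)=+1, hence ZCR 0 already

    freqs = np.fft.rfftfreq(mat.shape[1], d=1.0 / rate)
    mag_tot = spec.sum(axis=1)
    with np.errstate(invalid="ignore"):
        centroid = np.where(
            mag_tot > 0, (spec @ freqs) / np.where(mag_tot > 0, mag_tot, 1.0), 0.0
        )

    valid = energy > 0
    return FrameFeatureTable(
        energy=energy,
        entropy=entropy,
        zcr=zcr,
        centroid=centroid,
        frame_times_s=frames.frame_start_times_s.copy(),
        valid=valid,
        sample_rate_hz=rate,
    )


# --------------------------------------------------------------------------
# Mel spectrograms
# --------------------------------------------------------------------------

_MEL_DENOM = {"paper": 100.0, "htk_standard": 700.0}


def hz_to_mel(f, variant: str = "htk_standard"):
    """Map linear frequency (Hz) to Mel: 2595 * log10(1 + f / denom).

    ``htk_standard`` uses the conventional denominator 700; ``paper`` uses
    100 (an alternative printed constant, kept selectable).
    """
    if variant not in _MEL_DENOM:
        raise ValidationError(f"unknown Mel variant {variant!r}")
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValidationError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / _MEL_DENOM[variant])
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m, variant: str = "htk_standard"):
    if variant not in _MEL_DENOM:
        raise ValidationError(f"unknown Mel variant {variant!r}")
    m = np.asarray(m, dtype=np.float64)
    out = _MEL_DENOM[variant] * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def mel_filterbank(
    n_mels: int,
    n_fft: int,
    sample_rate_hz: int,
    variant: str = "htk_standard",
    fmin: float = 0.0,
    fmax: float | None = None,
) -> np.ndarray:
    """Triangular Mel filterbank, shape (n_mels, n_fft // 2 + 1).

    Filter centers are equally spaced on the Mel axis; adjacent triangles
    overlap so per-bin weights sum to at most one.  Any filter narrower
    than one FFT bin is given unit weight at its nearest bin so no row is
    all-zero (numerical safeguard for coarse FFT grids).
    """
    fmax = fmax if fmax is not None else sample_rate_hz / 2.0
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate_hz)
    mel_pts = np.linspace(
        hz_to_mel(fmin, variant), hz_to_mel(fmax, variant), n_mels + 2
    )
    hz_pts = mel_to_hz(mel_pts, variant)
    fb = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        rising = (freqs - lo) / max(ctr - lo, 1e-12)
        falling = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(rising, falling), 0.0, None)
        if not fb[m].any():
            fb[m, np.argmin(np.abs(freqs - ctr))] = 1.0
    return fb


@dataclass(frozen=True)
class MelConfig:
    n_mels: int = 128
    n_fft: int = 2048
    hop_ms: float = 10.0
    target_frames: int = 128
    log_scale: bool = True
    mel_variant: str = "htk_standard"
    fmin: float = 0.0
    fmax: float | None = None


@dataclass(frozen=True)
class MelSpectrogram:
    """A fixed-size (n_mels x target_frames) Mel image for one snore clip."""

    matrix: np.ndarray
    clip_id: str = ""
    label: str = "unknown"  # "normal" | "osahs" | "unknown"
    padded: bool = False
    config: MelConfig = field(default_factory=MelConfig)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("Mel spectrogram must be finite")


def _resize_time_axis(mat: np.ndarray, target: int) -> tuple[np.ndarray, bool]:
    """Linear interpolation of the time axis to ``target`` columns.

    Clips with fewer time frames than ``target`` are zero-padded on the
    right instead, and flagged.
    """
    n = mat.shape[1]
    if n == target:
        return mat, False
    if n < target:
        return np.pad(mat, ((0, 0), (0, target - n))), True
    src = np.linspace(0.0, n - 1.0, target)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    w = src - i0
    return mat[:, i0] * (1.0 - w) + mat[:, i1] * w, False


def mel_spectrogram(
    clip: AudioSignal,
    config: MelConfig | None = None,
    clip_id: str = "",
    label: str = "unknown",
) -> MelSpectrogram:
    """STFT power -> triangular Mel filterbank -> log(1 + S) -> 128x128."""
    config = config or MelConfig()
    x = clip.samples
    hop = max(1, int(round(clip.sample_rate_hz * config.hop_ms / 1000.0)))
    n_fft = config.n_fft
    if x.size < n_fft:
        raise ValidationError(
            f"clip of {x.size} samples is shorter than one FFT window ({n_fft})"
        )
    from scipy.signal.windows import hamming

    win = hamming(n_fft, sym=False)
    n_frames = (x.size - n_fft) // hop + 1
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # (frames, bins)
    fb = mel_filterbank(
        config.n_mels, n_fft, clip.sample_rate_hz, config.mel_variant,
        config.fmin, config.fmax,
    )
    mel = fb @ power.T  # (n_mels, frames)
    if config.log_scale:
        mel = np.log1p(mel)
    mat, was_padded = _resize_time_axis(mel, config.target_frames)
    return MelSpectrogram(
        matrix=mat, clip_id=clip_id, label=label, padded=was_padded, config=config
    )
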