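"""Synthetic nocturnal recordings and spectrogram datasets with ground truth.

Snore events are modelled as amplitude-modulated glottal pulse trains
(fundamental 60-180 Hz) band-limited to a low-to-mid formant band, so a
synthetic snore frame has elevated energy, a compact spectrum (low
entropy), a low spectral centroid and a smooth waveform (low ZCR) relative
to the pink-noise-plus-hum background — exactly the premises the endpoint
detector relies on.  Event placement follows a seeded renewal process and
the generator returns the planted intervals exactly, so a perfect detector
can score 100%.

Presets mirror common ward acoustics:

* ``original``  — mains hum plus intermittent broadband transients
                  (doors, call bells);
* ``denoised``  — near-clean stationary background;
* ``speech``    — ``original`` plus low-level conversational chatter.

All randomness flows from one seed via numpy's SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfilt

from .audio import AudioSignal
from .amff_ed import Segment, SegmentList
from .errors import ValidationError
from .features import MelConfig, MelSpectrogram, mel_spectrogram

__all__ = [
    "SnoreSimConfig",
    "GroundTruth",
    "preset",
    "synth_recording",
    "synth_spectrogram_dataset",
]


@dataclass(frozen=True)
class SnoreSimConfig:
    """Parameters of one synthetic nocturnal recording."""

    duration_s: float = 600.0
    sample_rate_hz: int = 16000
    event_rate_per_min: float = 6.0
    event_dur_s: tuple[float, float] = (0.6, 1.5)
    snore_f0_hz: tuple[float, float] = (60.0, 180.0)
    formant_band_hz: tuple[float, float] = (100.0, 800.0)
    snr_db: float = 10.0
    hum_level_db: float = -20.0  # hum RMS relative to pink-noise RMS
    speech_interference: bool = False
    speech_level_db: float = 5.0  # speech RMS relative to background RMS
    transient_rate_per_min: float = 0.0
    min_event_gap_s: float = 1.0
    background_rms: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValidationError("duration and sample rate must be positive")
        if not np.isfinite(self.snr_db):
            raise ValidationError("snr_db must be finite")
        lo, hi = self.event_dur_s
        if not 0 < lo <= hi:
            raise ValidationError("event_dur_s must be an increasing positive pair")
        mean_cycle = 60.0 / self.event_rate_per_min if self.event_rate_per_min else np.inf
        mean_dur = 0.5 * (lo + hi)
        if mean_cycle <= mean_dur + self.min_event_gap_s:
            raise ValidationError(
                "event schedule too dense: rate x duration leaves no idle time"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted event intervals and their per-event class labels."""

    events: SegmentList
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.labels and len(self.labels) != len(self.events):
            raise ValidationError("one label per event required")


_PRESETS = {
    "original": dict(hum_level_db=-6.0, transient_rate_per_min=2.0),
    "denoised": dict(hum_level_db=-20.0, transient_rate_per_min=0.0),
    "speech": dict(
        hum_level_db=-6.0, transient_rate_per_min=2.0, speech_interference=True
    ),
}


def preset(name: str, **overrides) -> SnoreSimConfig:
    """Named acoustic-condition presets (see module docstring)."""
    if name not in _PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return SnoreSimConfig(**{**_PRESETS[name], **overrides})


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise by spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / max(np.sqrt(np.mean(x**2)), 1e-30)


def _schedule_events(cfg: SnoreSimConfig, rng: np.random.Generator):
    """Renewal process: onset gaps = min gap + exponential idle time."""
    if cfg.event_rate_per_min <= 0:
        return []
    lo, hi = cfg.event_dur_s
    mean_cycle = 60.0 / cfg.event_rate_per_min
    scale = mean_cycle - 0.5 * (lo + hi) - cfg.min_event_gap_s
    events = []
    t = cfg.min_event_gap_s + rng.exponential(scale)
    while True:
        dur = rng.uniform(lo, hi)
        if t + dur > cfg.duration_s - 0.05:
            break
        events.append((t, t + dur))
        t = t + dur + cfg.min_event_gap_s + rng.exponential(scale)
    return events


def _snore_burst(dur_s: float, cfg: SnoreSimConfig, rng: np.random.Generator):
    """One amplitude-modulated, band-limited glottal pulse train, unit RMS."""
    fs = cfg.sample_rate_hz
    n = int(round(dur_s * fs))
    f0 = rng.uniform(*cfg.snore_f0_hz)
    t = np.arange(n) / fs
    # impulse train with mild period jitter, then formant-band resonance
    phase = 2 * np.pi * f0 * t + 0.3 * np.cumsum(rng.standard_normal(n)) / fs * f0
    pulses = np.cos(phase) + 0.5 * np.cos(2 * phase) + 0.25 * np.cos(3 * phase)
    lo, hi = cfg.formant_band_hz
    sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, pulses)
    x += 0.15 * sosfilt(sos, rng.standard_normal(n))  # breathy component
    # smooth attack/decay envelope with slow intra-event modulation
    att = max(1, int(0.15 * n))
    dec = max(1, int(0.25 * n))
    env = np.ones(n)
    env[:att] = 0.5 * (1 - np.cos(np.pi * np.arange(att) / att))
    env[-dec:] = 0.5 * (1 + np.cos(np.pi * np.arange(dec) / dec))
    env *= 1.0 + 0.2 * np.sin(2 * np.pi * rng.uniform(2, 5) * t)
    x *= env
    return x / max(np.sqrt(np.mean(x**2)), 1e-30)


def _speech_chatter(n: int, fs: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise with syllabic amplitude modulation and pauses."""
    sos = butter(2, [300.0, 3000.0], btype="bandpass", fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n))
    t = np.arange(n) / fs
    syllabic = 0.5 * (1 + np.sin(2 * np.pi * 4.0 * t + rng.uniform(0, 2 * np.pi)))
    # utterance on/off gating: ~2 s talk spurts separated by ~3 s pauses
    gate = np.zeros(n)
    pos = 0
    while pos < n:
        talk = int(rng.uniform(1.0, 3.0) * fs)
        pause = int(rng.uniform(2.0, 5.0) * fs)
        gate[pos : pos + talk] = 1.0
        pos += talk + pause
    x *= syllabic * gate
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-30)


def synth_recording(config: SnoreSimConfig) -> tuple[AudioSignal, GroundTruth]:
    """Render one recording and its exact ground-truth event list."""
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    root = np.random.SeedSequence(config.seed)
    keys = root.spawn(6)
    rng_bg, rng_sched, rng_ev, rng_tr, rng_sp, rng_hum = (
        np.random.default_rng(k) for k in keys
    )

    bg = _pink_noise(n, rng_bg) * config.background_rms
    hum_rms = config.background_rms * 10.0 ** (config.hum_level_db / 20.0)
    t = np.arange(n) / fs
    hum_phase = rng_hum.uniform(0, 2 * np.pi, size=3)
    hum = sum(
        a * np.sin(2 * np.pi * f * t + p)
        for a, f, p in zip((1.0, 0.4, 0.2), (50.0, 100.0, 150.0), hum_phase)
    )
    hum *= hum_rms / max(np.sqrt(np.mean(hum**2)), 1e-30)
    x = bg + hum
    bg_rms = np.sqrt(np.mean(x**2))

    events = _schedule_events(config, rng_sched)
    amp = bg_rms * 10.0 ** (config.snr_db / 20.0)
    for t0, t1 in events:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        burst = _snore_burst((i1 - i0) / fs, config, rng_ev)
        x[i0 : i0 + burst.size] += amp * burst

    if config.transient_rate_per_min > 0:
        n_tr = rng_tr.poisson(config.transient_rate_per_min * config.duration_s / 60.0)
        for _ in range(n_tr):
            dur = int(rng_tr.uniform(0.05, 0.15) * fs)
            pos = int(rng_tr.uniform(0, max(1, n - dur)))
            burst = rng_tr.standard_normal(dur) * np.exp(
                -np.arange(dur) / (0.03 * fs)
            )
            burst *= bg_rms * 10.0 ** (15.0 / 20.0) / max(
                np.sqrt(np.mean(burst**2)), 1e-30
            )
            x[pos : pos + dur] += burst

    if config.speech_interference:
        speech = _speech_chatter(n, fs, rng_sp)
        x += speech * bg_rms * 10.0 ** (config.speech_level_db / 20.0)

    peak = np.max(np.abs(x))
    if peak > 0.99:  # headroom, affects amplitude only
        x *= 0.99 / peak

    truth = GroundTruth(
        events=SegmentList(Segment(t0, t1) for t0, t1 in events),
        labels=tuple("normal_snore" for _ in events),
    )
    return AudioSignal(x, fs), truth


# --------------------------------------------------------------------------
# Two-class spectrogram dataset for classifier smoke training
# --------------------------------------------------------------------------


def _class_clip(
    label: str, separation: str, fs: int, dur_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Render one clip: regular low-band bursts (normal) vs irregular,
    band-shifted bursts with silence gaps (OSAHS surrogate)."""
    n = int(round(dur_s * fs))
    x = 0.005 * _pink_noise(n, rng)
    if label == "normal":
        band = (100.0, 500.0)
        f0 = rng.uniform(80, 140)
        n_bursts, jitter = 3, 0.02
    else:
        band = (300.0, 900.0) if separation == "easy" else (200.0, 700.0)
        f0 = rng.uniform(60, 100)
        n_bursts, jitter = 2, 0.15
    cfg = SnoreSimConfig(
        duration_s=dur_s, sample_rate_hz=fs, snore_f0_hz=(f0, f0 + 1),
        formant_band_hz=band,
    )
    slot = dur_s / n_bursts
    for b in range(n_bursts):
        dur = rng.uniform(0.3, 0.45) * slot
        t0 = b * slot + rng.uniform(0, jitter * slot)
        if label == "osahs" and b == n_bursts - 1 and rng.uniform() < 0.5:
            t0 += 0.3 * slot  # irregular timing / apnea-like silence gap
        i0 = int(t0 * fs)
        burst = _snore_burst(dur, cfg, rng) * rng.uniform(0.15, 0.3)
        end = min(n, i0 + burst.size)
        x[i0:end] += burst[: end - i0]
    return x


def synth_spectrogram_dataset(
    n_per_class: int,
    separation: str = "easy",
    seed: int = 0,
    sample_rate_hz: int = 16000,
    clip_s: float = 2.0,
    mel_config: MelConfig | None = None,
    return_audio: bool = False,
):
    """Balanced labelled Mel-spectrogram collection (normal vs osahs).

    ``easy`` classes are separable by the band-energy ratio alone; ``hard``
    moves the pathological band down so the classes overlap spectrally.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if separation not in ("easy", "hard"):
        raise ValidationError("separation must be 'easy' or 'hard'")
    mel_config = mel_config or MelConfig()
    root = np.random.SeedSequence(seed)
    keys = iter(root.spawn(2 * n_per_class))
    out, audio = [], []
    for label in ("normal", "osahs"):
        for i in range(n_per_class):
            rng = np.random.default_rng(next(keys))
            x = _class_clip(label, separation, sample_rate_hz, clip_s, rng)
            clip = AudioSignal(x, sample_rate_hz)
            out.append(
                mel_spectrogram(
                    clip, mel_config, clip_id=f"{label}_{i:04d}", label=label
                )
            )
            if return_audio:
                audio.append(clip)
    return (out, audio) if return_audio else out
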