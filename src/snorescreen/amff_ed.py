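"""Adaptive multi-feature snore endpoint detection (AMFF-ED).

The detector walks a long recording in 2-minute analysis windows.  Within
each window it derives one adaptive threshold per feature from that
window's own feature distribution, then votes each frame:

    S_i = I(E_i >= T_E) + I(H_i <= T_H) + I(ZCR_i <= T_ZCR) + I(C_i <= T_C)

and marks the frame as snoring when S_i >= 3 (by default).  Maximal runs of
snoring frames become candidate segments; neighbouring segments closer
than 0.3 s are merged and segments shorter than 0.3 s are discarded.

Two threshold conventions are provided (see :func:`compute_thresholds`):

* ``discriminative`` (default): each threshold sits on the snore side of
  the window distribution — energy a fixed factor (+7 dB) above the
  window's median short-time energy (an SNR-style floor gate), centroid
  at the lower quartile, entropy/ZCR at mean minus half a standard
  deviation.  Because snoring frames are a minority with elevated energy,
  low centroid, low entropy and low ZCR, this separates them from the
  background regardless of the snore duty cycle.
* ``as_printed``: energy at the lower decile, centroid at the upper
  quartile, entropy/ZCR at mean plus half a standard deviation.  These
  gates each pass most of the background, so the convention is kept only
  for comparison and for pinning the percentile arithmetic.

With ``energy_mandatory`` (default) the energy criterion is a necessary
condition and the spectral cues corroborate: a frame is snoring when its
energy clears the floor and at least two of the three spectral gates
agree.  The three spectral features are strongly correlated on
low-frequency ambient noise, so without the energy requirement they can
outvote it.  Isolated sub-0.1 s runs are discarded before gap merging so
scattered single-frame marks cannot chain through the 0.3 s merge rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .audio import AudioSignal
from .errors import ValidationError
from .features import FrameFeatureTable, compute_feature_table
from .preprocess import (
    PreprocessConfig,
    denoise,
    frame_params,
    frame_signal,
)

__all__ = [
    "ThresholdSet",
    "Segment",
    "SegmentList",
    "DetectorConfig",
    "compute_thresholds",
    "frame_votes",
    "runs_to_segments",
    "merge_gaps",
    "filter_short",
    "detect",
    "BASELINE_ENERGY_ZCR",
]

ALL_FEATURES = ("energy", "entropy", "zcr", "centroid")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-window adaptive thresholds T_E, T_H, T_ZCR, T_C."""

    t_energy: float
    t_entropy: float
    t_zcr: float
    t_centroid: float
    window_index: int = 0

    def __post_init__(self) -> None:
        vals = (self.t_energy, self.t_entropy, self.t_zcr, self.t_centroid)
        if not all(np.isfinite(vals)):
            raise ValidationError("thresholds must be finite")


@dataclass(frozen=True)
class Segment:
    """A half-open snore interval [t_start_s, t_end_s)."""

    t_start_s: float
    t_end_s: float
    source_window: int = field(default=0, compare=False)
    n_frames: int = field(default=0, compare=False)
    mean_vote: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if not self.t_end_s > self.t_start_s:
            raise ValidationError("segment must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


class SegmentList(Sequence):
    """Ordered, pairwise-disjoint sequence of segments."""

    def __init__(self, segments: Iterable[Segment] = ()):
        segs = list(segments)
        for a, b in zip(segs, segs[1:]):
            if b.t_start_s < a.t_end_s:
                raise ValidationError("segments must be sorted and disjoint")
        self._segments = segs

    def __len__(self) -> int:
        return len(self._segments)

    def __getitem__(self, i):
        out = self._segments[i]
        return SegmentList(out) if isinstance(i, slice) else out

    def __iter__(self) -> Iterator[Segment]:
        return iter(self._segments)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SegmentList):
            return NotImplemented
        return self._segments == other._segments

    def __repr__(self) -> str:
        return f"SegmentList({self._segments!r})"

    def intervals(self) -> np.ndarray:
        """(n, 2) array of [t_start, t_end)."""
        if not self._segments:
            return np.empty((0, 2))
        return np.array([[s.t_start_s, s.t_end_s] for s in self._segments])

    def shifted(self, dt: float) -> "SegmentList":
        return SegmentList(
            replace(s, t_start_s=s.t_start_s + dt, t_end_s=s.t_end_s + dt)
            for s in self._segments
        )


@dataclass(frozen=True)
class DetectorConfig:
    """AMFF-ED settings; numeric defaults follow the published constants."""

    analysis_window_s: float = 120.0
    analysis_step_s: float = 120.0
    vote_threshold: int = 3
    gap_s: float = 0.3
    min_dur_s: float = 0.3
    energy_percentile: float = 10.0
    centroid_percentile: float = 75.0
    spread_coeff: float = 0.5
    energy_floor_mult: float = 5.0  # energy gate: mult x median noise energy (+7 dB)
    energy_mandatory: bool = True
    min_raw_run_s: float = 0.1  # drop shorter raw runs before gap merging
    threshold_mode: str = "discriminative"  # or "as_printed"
    features: tuple[str, ...] = ALL_FEATURES

    def __post_init__(self) -> None:
        if not 1 <= self.vote_threshold <= len(self.features):
            raise ValidationError("vote_threshold must be within the feature count")
        for p in (self.energy_percentile, self.centroid_percentile):
            if not 0 < p < 100:
                raise ValidationError("percentiles must lie in (0, 100)")
        if min(self.analysis_window_s, self.analysis_step_s,
               self.gap_s, self.min_dur_s) <= 0:
            raise ValidationError("durations must be positive")
        if self.threshold_mode not in ("discriminative", "as_printed"):
            raise ValidationError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.energy_floor_mult <= 0 or self.min_raw_run_s < 0:
            raise ValidationError("energy_floor_mult must be > 0, min_raw_run_s >= 0")
        unknown = set(self.features) - set(ALL_FEATURES)
        if unknown:
            raise ValidationError(f"unknown features {sorted(unknown)}")


#: The conventional short-time-energy + ZCR comparison detector: classical
#: dual-cue endpoint detection treats either cue (elevated energy, or the
#: low zero-crossing rate typical of voiced/snore frames) as sufficient
#: evidence, extending boundaries through low-energy stretches.
BASELINE_ENERGY_ZCR = DetectorConfig(
    features=("energy", "zcr"), vote_threshold=1, energy_mandatory=False
)


def compute_thresholds(
    features: FrameFeatureTable,
    config: DetectorConfig | None = None,
    window_index: int = 0,
    reference_energy: np.ndarray | None = None,
) -> ThresholdSet:
    """Adaptive statistical thresholds for one analysis window.

    ``as_printed``:      T_E = P10(E),        T_C = P75(C),  T = mu + 0.5 sigma
    ``discriminative``:  T_E = 5 x median(E), T_C = P25(C),  T = mu - 0.5 sigma

    Percentiles use linear interpolation between order statistics; sigma is
    the population standard deviation.  The discriminative energy rule is a
    noise-floor gate (+7 dB over the window's median frame energy), which
    stays valid whatever fraction of the window is actually snoring.  When
    the features come from a spectrally subtracted signal, pass the raw
    (pre-subtraction) frame energies as ``reference_energy``: subtraction
    rescales the background arbitrarily, so the floor must reference the
    original noise level.
    """
    config = config or DetectorConfig()
    if len(features) < 2:
        raise ValidationError("threshold estimation needs at least two frames")
    c = config.spread_coeff
    if config.threshold_mode == "as_printed":
        sign = +1.0
        t_e = float(np.percentile(features.energy, config.energy_percentile))
        t_c = float(np.percentile(features.centroid, config.centroid_percentile))
    else:  # discriminative: mirror each rule toward the snore side
        sign = -1.0
        e_ref = features.energy if reference_energy is None else reference_energy
        t_e = float(config.energy_floor_mult * np.median(e_ref))
        t_c = float(
            np.percentile(features.centroid, 100.0 - config.centroid_percentile)
        )
    t_h = float(np.mean(features.entropy) + sign * c * np.std(features.entropy))
    t_z = float(np.mean(features.zcr) + sign * c * np.std(features.zcr))
    return ThresholdSet(t_e, t_h, t_z, t_c, window_index=window_index)


def frame_votes(
    features: FrameFeatureTable,
    thresholds: ThresholdSet,
    config: DetectorConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vote count S_i in {0..4} per frame and the snore-frame mask.

    Comparisons are inclusive; frames flagged invalid (all-zero) vote 0.
    With ``energy_mandatory`` the mask additionally requires the energy
    criterion itself, not just any ``vote_threshold`` of the cues.
    """
    config = config or DetectorConfig()
    tests = {
        "energy": features.energy >= thresholds.t_energy,
        "entropy": features.entropy <= thresholds.t_entropy,
        "zcr": features.zcr <= thresholds.t_zcr,
        "centroid": features.centroid <= thresholds.t_centroid,
    }
    votes = np.zeros(len(features), dtype=np.int64)
    for name in config.features:
        votes += tests[name].astype(np.int64)
    votes = np.where(features.valid, votes, 0)
    mask = votes >= config.vote_threshold
    if config.energy_mandatory and "energy" in config.features:
        mask &= tests["energy"] & features.valid
    return votes, mask


def runs_to_segments(
    mask: np.ndarray,
    frame_times_s: np.ndarray,
    hop_s: float,
    frame_len_s: float,
    source_window: int = 0,
    votes: np.ndarray | None = None,
) -> SegmentList:
    """Turn maximal runs of true frames into raw half-open segments.

    A run spanning frames i..j becomes [time(i), time(j) + frame_len_s).
    """
    mask = np.asarray(mask, dtype=bool)
    frame_times_s = np.asarray(frame_times_s, dtype=np.float64)
    if mask.size != frame_times_s.size:
        raise ValidationError("mask and frame times must have equal length")
    if mask.size == 0 or not mask.any():
        return SegmentList()
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1  # inclusive frame indices
    segs: list[Segment] = []
    for i0, i1 in zip(starts, ends):
        mv = float(np.mean(votes[i0 : i1 + 1])) if votes is not None else float("nan")
        seg = Segment(
            t_start_s=float(frame_times_s[i0]),
            t_end_s=float(frame_times_s[i1] + frame_len_s),
            source_window=source_window,
            n_frames=int(i1 - i0 + 1),
            mean_vote=mv,
        )
        # overlapping frames (hop < frame length) can make runs separated by
        # very few false frames overlap in time; union them immediately
        if segs and seg.t_start_s < segs[-1].t_end_s:
            prev = segs[-1]
            n_tot = prev.n_frames + seg.n_frames
            mv_u = float("nan")
            if votes is not None and n_tot:
                mv_u = (prev.mean_vote * prev.n_frames + mv * seg.n_frames) / n_tot
            segs[-1] = Segment(
                prev.t_start_s, max(prev.t_end_s, seg.t_end_s),
                source_window, n_tot, mv_u,
            )
        else:
            segs.append(seg)
    return SegmentList(segs)


def merge_gaps(segments: SegmentList, gap_s: float = 0.3) -> SegmentList:
    """Union consecutive segments whose gap is shorter than ``gap_s``.

    Idempotent: the output contains no gap below ``gap_s``.
    """
    segs = list(segments)  # SegmentList constructor enforces sorted/disjoint
    if not segs:
        return SegmentList()
    merged = [segs[0]]
    for seg in segs[1:]:
        prev = merged[-1]
        if seg.t_start_s - prev.t_end_s < gap_s:
            n = prev.n_frames + seg.n_frames
            mv = float("nan")
            if n and np.isfinite(prev.mean_vote) and np.isfinite(seg.mean_vote):
                mv = (prev.mean_vote * prev.n_frames + seg.mean_vote * seg.n_frames) / n
            merged[-1] = Segment(
                prev.t_start_s, seg.t_end_s, prev.source_window, n, mv
            )
        else:
            merged.append(seg)
    return SegmentList(merged)


_TIME_EPS = 1e-12  # absorbs float rounding at inclusive duration/gap boundaries


def filter_short(segments: SegmentList, min_dur_s: float = 0.3) -> SegmentList:
    """Keep exactly the segments with duration >= ``min_dur_s`` (inclusive)."""
    return SegmentList(s for s in segments if s.duration_s >= min_dur_s - _TIME_EPS)


def _iter_windows(n_samples: int, rate: int, config: DetectorConfig):
    win = int(round(config.analysis_window_s * rate))
    step = int(round(config.analysis_step_s * rate))
    start = 0
    while start < n_samples:
        yield start, min(start + win, n_samples)
        start += step


def detect(
    signal: AudioSignal,
    config: DetectorConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> SegmentList:
    """Run the full detector over a recording.

    Per 2-minute window: optional spectral-subtraction denoising (noise
    estimated within the window), framing, feature extraction, adaptive
    thresholds and voting.  Frame masks are concatenated across windows and
    post-processing (gap merge, minimum duration) is applied globally, so
    events straddling a window boundary survive.  Segment times refer to the
    original timeline.
    """
    config = config or DetectorConfig()
    pre = preprocess_config or PreprocessConfig()
    rate = signal.sample_rate_hz
    n, h = frame_params(rate, pre.frame_ms, pre.hop_ms)

    all_times, all_mask, all_votes = [], [], []
    for w_idx, (lo, hi) in enumerate(_iter_windows(signal.samples.size, rate, config)):
        chunk = signal.samples[lo:hi]
        if chunk.size < n + h:  # too short to threshold (needs >= 2 frames)
            continue
        win_sig = AudioSignal(chunk, rate)
        ref_energy = None
        if pre.denoise:
            raw_frames = frame_signal(win_sig, pre.frame_ms, pre.hop_ms)
            ref_energy = np.sum(raw_frames.frames**2, axis=1)
            win_sig = denoise(win_sig, pre)
        frames = frame_signal(win_sig, pre.frame_ms, pre.hop_ms)
        feats = compute_feature_table(frames, rate)
        thr = compute_thresholds(
            feats, config, window_index=w_idx, reference_energy=ref_energy
        )
        votes, mask = frame_votes(feats, thr, config)
        all_times.append(feats.frame_times_s + lo / rate)
        all_mask.append(mask)
        all_votes.append(votes)

    if not all_times:
        return SegmentList()
    times = np.concatenate(all_times)
    mask = np.concatenate(all_mask)
    votes = np.concatenate(all_votes)
    raw = runs_to_segments(mask, times, h / rate, n / rate, votes=votes)
    if config.min_raw_run_s > 0:
        raw = filter_short(raw, config.min_raw_run_s)
    return filter_short(merge_gaps(raw, config.gap_s), config.min_dur_s)
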