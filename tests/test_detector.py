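"""Adaptive thresholds, frame voting, post-processing and detect()."""

import numpy as np
import pytest

import snorescreen as ss
from snorescreen.amff_ed import DetectorConfig, Segment, SegmentList, _iter_windows
from snorescreen.errors import ValidationError
from snorescreen.features import FrameFeatureTable
from snorescreen.preprocess import PreprocessConfig


AS_PRINTED = DetectorConfig(threshold_mode="as_printed", energy_mandatory=False)


def make_table(e, h, z, c, rate=16000):
    e = np.asarray(e, dtype=float)
    n = e.size
    return FrameFeatureTable(
        energy=e,
        entropy=np.broadcast_to(np.asarray(h, dtype=float), (n,)).copy(),
        zcr=np.broadcast_to(np.asarray(z, dtype=float), (n,)).copy(),
        centroid=np.broadcast_to(np.asarray(c, dtype=float), (n,)).copy(),
        frame_times_s=np.arange(n) * 0.01,
        valid=e > 0,
        sample_rate_hz=rate,
    )


class TestThresholds:
    def test_degenerate_constant_features_as_printed(self):
        table = make_table(np.full(10, 2.0), 3.0, 0.1, 500.0)
        thr = ss.compute_thresholds(table, AS_PRINTED)
        assert thr.t_energy == 2.0
        assert thr.t_entropy == 3.0
        assert thr.t_zcr == 0.1
        assert thr.t_centroid == 500.0

    def test_degenerate_constant_features_discriminative(self):
        table = make_table(np.full(10, 2.0), 3.0, 0.1, 500.0)
        thr = ss.compute_thresholds(table, DetectorConfig())
        assert thr.t_energy == 5.0 * 2.0  # +7 dB noise-floor gate
        assert thr.t_entropy == 3.0
        assert thr.t_zcr == 0.1
        assert thr.t_centroid == 500.0

    def test_energy_percentile_linear_interpolation(self):
        table = make_table(np.arange(1.0, 101.0), 1.0, 0.1, 100.0)
        thr = ss.compute_thresholds(table, AS_PRINTED)
        assert np.isclose(thr.t_energy, 10.9)

    def test_mean_plus_half_sigma_standard_normal(self):
        rng = np.random.default_rng(0)
        h = rng.standard_normal(100_000)
        table = make_table(np.ones(h.size), h, 0.1, 100.0)
        thr = ss.compute_thresholds(table, AS_PRINTED)
        assert abs(thr.t_entropy - 0.5) < 0.02

    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            ss.compute_thresholds(make_table([1.0], 1.0, 0.1, 100.0))


class TestFrameVotes:
    def test_boundary_frame_collects_all_votes(self):
        table = make_table(np.full(4, 2.0), 3.0, 0.1, 500.0)
        thr = ss.compute_thresholds(table, AS_PRINTED)
        votes, mask = ss.frame_votes(table, thr, AS_PRINTED)
        assert np.all(votes == 4)
        assert np.all(mask)

    def test_frame_failing_everything_votes_zero(self):
        table = make_table(np.full(3, 2.0), 3.0, 0.1, 500.0)
        thr = ss.ThresholdSet(t_energy=5.0, t_entropy=1.0, t_zcr=0.01, t_centroid=100.0)
        votes, mask = ss.frame_votes(table, thr, AS_PRINTED)
        assert np.all(votes == 0)
        assert not mask.any()

    def test_vectorized_votes_equal_per_frame_loop(self):
        rng = np.random.default_rng(1)
        n = 1000
        table = make_table(
            rng.uniform(0, 10, n), rng.uniform(0, 5, n),
            rng.uniform(0, 0.5, n), rng.uniform(0, 8000, n),
        )
        for config in (AS_PRINTED, DetectorConfig()):
            thr = ss.compute_thresholds(table, config)
            votes, mask = ss.frame_votes(table, thr, config)
            for i in range(n):
                s = (
                    int(table.energy[i] >= thr.t_energy)
                    + int(table.entropy[i] <= thr.t_entropy)
                    + int(table.zcr[i] <= thr.t_zcr)
                    + int(table.centroid[i] <= thr.t_centroid)
                )
                if not table.valid[i]:
                    s = 0
                assert votes[i] == s
                expect = s >= config.vote_threshold
                if config.energy_mandatory:
                    expect = expect and table.energy[i] >= thr.t_energy
                assert mask[i] == expect

    def test_raising_vote_threshold_shrinks_mask(self):
        rng = np.random.default_rng(2)
        n = 500
        table = make_table(
            rng.uniform(0, 10, n), rng.uniform(0, 5, n),
            rng.uniform(0, 0.5, n), rng.uniform(0, 8000, n),
        )
        prev = None
        for vt in (1, 2, 3, 4):
            config = DetectorConfig(vote_threshold=vt)
            thr = ss.compute_thresholds(table, config)
            _, mask = ss.frame_votes(table, thr, config)
            if prev is not None:
                assert np.all(mask <= prev)  # mask only ever shrinks
            prev = mask

    def test_invalid_frames_never_vote(self):
        e = np.array([0.0, 1.0, 0.0])
        table = make_table(e, 0.0, 0.0, 0.0)
        thr = ss.ThresholdSet(0.0, 10.0, 1.0, 9000.0)
        votes, mask = ss.frame_votes(table, thr, AS_PRINTED)
        assert votes[0] == votes[2] == 0
        assert votes[1] == 4


class TestRunsToSegments:
    def test_all_false_mask_empty(self):
        out = ss.runs_to_segments(np.zeros(10, bool), np.arange(10) * 0.01, 0.01, 0.025)
        assert len(out) == 0

    def test_single_run_arithmetic(self):
        mask = np.zeros(30, bool)
        mask[10:20] = True
        out = ss.runs_to_segments(mask, np.arange(30) * 0.01, 0.01, 0.025)
        assert len(out) == 1
        assert np.isclose(out[0].t_start_s, 0.100)
        assert np.isclose(out[0].t_end_s, 0.215)
        assert out[0].n_frames == 10

    def test_two_runs_with_nonoverlapping_frames(self):
        mask = np.array([True, False, True])
        out = ss.runs_to_segments(mask, np.arange(3) * 0.025, 0.025, 0.025)
        assert len(out) == 2

    def test_overlapping_frame_runs_are_unioned(self):
        # 25 ms frames with 10 ms hop: runs one false frame apart overlap
        mask = np.array([True, False, True])
        out = ss.runs_to_segments(mask, np.arange(3) * 0.01, 0.01, 0.025)
        assert len(out) == 1
        assert np.isclose(out[0].t_end_s, 0.045)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            ss.runs_to_segments(np.ones(3, bool), np.arange(4) * 0.01, 0.01, 0.025)


def random_segment_list(rng, n_max=12, allow_close=True):
    t = 0.0
    segs = []
    for _ in range(int(rng.integers(0, n_max))):
        t += rng.uniform(0.01 if allow_close else 0.35, 1.0)
        dur = rng.uniform(0.02, 1.0)
        segs.append(Segment(t, t + dur))
        t += dur
    return SegmentList(segs)


class TestPostProcessing:
    def test_gap_below_threshold_merges(self):
        merged = ss.merge_gaps(
            SegmentList([Segment(0.0, 0.5), Segment(0.7, 1.2)]), gap_s=0.3
        )
        assert len(merged) == 1
        assert merged[0].t_start_s == 0.0 and merged[0].t_end_s == 1.2

    def test_gap_at_or_above_threshold_kept(self):
        segs = SegmentList([Segment(0.0, 0.5), Segment(0.9, 1.2)])
        assert list(ss.merge_gaps(segs, 0.3)) == list(segs)
        exact = SegmentList([Segment(0.0, 0.5), Segment(0.8, 1.2)])
        assert len(ss.merge_gaps(exact, 0.3)) == 2  # gap == 0.3 not merged

    @pytest.mark.parametrize("seed", range(100))
    def test_merge_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        once = ss.merge_gaps(random_segment_list(rng), 0.3)
        twice = ss.merge_gaps(once, 0.3)
        assert list(once) == list(twice)

    def test_min_duration_filtering(self):
        segs = SegmentList([Segment(2.0, 2.2), Segment(3.0, 3.3), Segment(4.0, 5.0)])
        kept = ss.filter_short(segs, 0.3)
        assert [s.t_start_s for s in kept] == [3.0, 4.0]  # 0.3 s kept inclusively

    def test_filter_count_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            segs = random_segment_list(rng)
            kept = ss.filter_short(segs, 0.3)
            assert len(kept) == sum(1 for s in segs if s.duration_s >= 0.3)

    @pytest.mark.parametrize("seed", range(200))
    def test_postprocessing_output_invariants_fuzz(self, seed):
        """Random frame masks through the full post-processing chain."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 400))
        mask = rng.uniform(size=n) < rng.uniform(0.05, 0.9)
        times = np.arange(n) * 0.01
        raw = ss.runs_to_segments(mask, times, 0.01, 0.025)
        out = ss.filter_short(ss.merge_gaps(raw, 0.3), 0.3)
        ivals = out.intervals()
        assert np.all(ivals[:, 1] - ivals[:, 0] >= 0.3 - 1e-12)
        if len(out) > 1:
            gaps = ivals[1:, 0] - ivals[:-1, 1]
            assert np.all(gaps >= 0.3 - 1e-12)
            assert np.all(np.diff(ivals[:, 0]) > 0)


class TestDetect:
    def test_pure_noise_has_few_false_positives(self):
        fp_counts = []
        for seed in range(20):
            cfg = ss.SnoreSimConfig(
                duration_s=600.0, event_rate_per_min=0.0, seed=seed + 100
            )
            signal, truth = ss.synth_recording(cfg)
            assert len(truth.events) == 0
            fp_counts.append(len(ss.detect(signal)))
        assert np.mean(fp_counts) <= 2.0

    def test_short_recording_processed_as_single_window(self):
        cfg = ss.preset("denoised", duration_s=30.0, seed=1, event_rate_per_min=8.0)
        signal, truth = ss.synth_recording(cfg)
        segs = ss.detect(signal)
        assert len(segs) >= 1
        ev = ss.endpoint_accuracy(segs, truth.events)
        assert ev.recall >= 0.5

    def test_output_invariants_on_synthetic_nights(self):
        for seed in (3, 4):
            cfg = ss.preset("original", duration_s=180.0, seed=seed)
            signal, _ = ss.synth_recording(cfg)
            out = ss.detect(signal)
            ivals = out.intervals()
            assert np.all(ivals[:, 1] - ivals[:, 0] >= 0.3 - 1e-12)
            if len(out) > 1:
                assert np.all(ivals[1:, 0] - ivals[:-1, 1] >= 0.3 - 1e-12)

    def test_amplitude_invariance(self):
        cfg = ss.preset("denoised", duration_s=60.0, seed=9)
        signal, _ = ss.synth_recording(cfg)
        a = ss.detect(signal)
        b = ss.detect(signal.scaled(8.0))  # exact power-of-two scaling
        assert list(a) == list(b)

    def test_windows_are_statistically_independent(self):
        # identical audio placed in different 2-min windows yields identical
        # (shifted) detections: one window's statistics never leak into another
        cfg_a = ss.preset("denoised", duration_s=120.0, seed=11)
        cfg_b = ss.preset("denoised", duration_s=120.0, seed=12, snr_db=20.0)
        sig_a, _ = ss.synth_recording(cfg_a)
        sig_b, _ = ss.synth_recording(cfg_b)
        ab = ss.AudioSignal(np.concatenate([sig_a.samples, sig_b.samples]), 16000)
        ba = ss.AudioSignal(np.concatenate([sig_b.samples, sig_a.samples]), 16000)
        pre = PreprocessConfig(denoise=False)
        segs_ab = ss.detect(ab, preprocess_config=pre)
        segs_ba = ss.detect(ba, preprocess_config=pre)
        a_from_ab = [(s.t_start_s, s.t_end_s) for s in segs_ab if s.t_end_s < 119.9]
        a_from_ba = [
            (s.t_start_s - 120.0, s.t_end_s - 120.0)
            for s in segs_ba
            if s.t_start_s > 120.1
        ]
        assert np.allclose(np.array(a_from_ab), np.array(a_from_ba), atol=1e-9)

    def test_window_iteration_covers_signal(self):
        cfg = DetectorConfig()
        spans = list(_iter_windows(16000 * 300, 16000, cfg))
        assert spans[0] == (0, 16000 * 120)
        assert spans[-1][1] == 16000 * 300
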