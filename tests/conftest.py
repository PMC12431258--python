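"""Shared fixtures: small audio signals and the heavy end-to-end studies.

The synthetic detection study (20 seeds x three detector/preset
combinations) and the classifier smoke trainings are computed once per
session and shared between the module tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import snorescreen as ss
from snorescreen.amff_ed import BASELINE_ENERGY_ZCR


N_STUDY_SEEDS = 20
STUDY_DURATION_S = 600.0


def _tone(freq_hz: float, duration_s: float, rate: int = 16000, amp: float = 0.5):
    t = np.arange(int(duration_s * rate)) / rate
    return ss.AudioSignal(amp * np.sin(2 * np.pi * freq_hz * t), rate)


@pytest.fixture
def tone_signal():
    return _tone(440.0, 1.0)


@pytest.fixture
def make_tone():
    return _tone


@pytest.fixture(scope="session")
def detection_study():
    """Endpoint-detection results over 20 synthetic 10-minute nights.

    For every seed: the `denoised` preset is scored with the full detector
    and with the conventional energy+ZCR baseline, and the `speech` preset
    with the full detector.  Returns lists of DetectionEval per condition.
    """
    results = {"denoised": [], "speech": [], "baseline": []}
    for seed in range(1, N_STUDY_SEEDS + 1):
        cfg = ss.preset("denoised", duration_s=STUDY_DURATION_S, seed=seed)
        signal, truth = ss.synth_recording(cfg)
        segs = ss.detect(signal)
        results["denoised"].append(ss.endpoint_accuracy(segs, truth.events))
        base = ss.detect(signal, BASELINE_ENERGY_ZCR)
        results["baseline"].append(ss.endpoint_accuracy(base, truth.events))
        del signal

        cfg = ss.preset("speech", duration_s=STUDY_DURATION_S, seed=seed)
        signal, truth = ss.synth_recording(cfg)
        segs = ss.detect(signal)
        results["speech"].append(ss.endpoint_accuracy(segs, truth.events))
        del signal
    return results


def pooled_accuracy(evals) -> float:
    """Eq.-17-style pooled accuracy: total correct / total detected * 100."""
    f_r = sum(e.f_r for e in evals)
    f_a = sum(e.f_a for e in evals)
    return 100.0 * f_r / f_a if f_a else float("nan")


@pytest.fixture(scope="session")
def smoke_dataset():
    """40-clip easily separable two-class spectrogram dataset."""
    return ss.synth_spectrogram_dataset(20, "easy", seed=7)


@pytest.fixture(scope="session")
def smoke_training(smoke_dataset):
    """One full smoke training run on the 40-clip dataset.

    Eight epochs suffice on the separable dataset (convergence is by
    epoch two; the remainder settle the batch-norm running statistics),
    comfortably within a 30-epoch budget.
    """
    model = ss.build_model(seed=3)
    tc = ss.TrainConfig(max_epochs=8, seed=3)
    return ss.train(model, smoke_dataset, tc, init_seed=3)
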