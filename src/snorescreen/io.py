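"""Tabular I/O for segment lists, feature tables and spectrogram datasets.

Interval files are TSV with columns t_start_s, t_end_s and optionally
duration_s, mean_vote and label; the Audacity label-track format
(start<TAB>end<TAB>label) is supported for import and export.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .amff_ed import Segment, SegmentList
from .errors import ValidationError
from .features import MelConfig, MelSpectrogram

__all__ = [
    "write_segments_tsv",
    "read_segments_tsv",
    "write_audacity_labels",
    "write_mel_dataset",
    "read_mel_dataset",
]


def write_segments_tsv(path, segments: SegmentList, labels=None) -> None:
    rows = {
        "t_start_s": [s.t_start_s for s in segments],
        "t_end_s": [s.t_end_s for s in segments],
        "duration_s": [s.duration_s for s in segments],
        "mean_vote": [s.mean_vote for s in segments],
    }
    if labels is not None:
        rows["label"] = list(labels)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_segments_tsv(path) -> tuple[SegmentList, list | None]:
    """Read an interval TSV (or Audacity label track) into a SegmentList."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - surfaced as schema error
        raise ValidationError(f"cannot parse interval file {path}: {exc}") from exc
    cols = [c.lower() for c in df.columns]
    if "t_start_s" in cols and "t_end_s" in cols:
        df.columns = cols
    elif df.shape[1] >= 2 and _looks_like_audacity(path):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["t_start_s", "t_end_s", "label"]
        )
    else:
        raise ValidationError(
            f"{path}: expected columns t_start_s/t_end_s or an Audacity label track"
        )
    try:
        segs = SegmentList(
            Segment(float(r.t_start_s), float(r.t_end_s))
            for r in df.itertuples(index=False)
        )
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed interval values: {exc}") from exc
    labels = df["label"].tolist() if "label" in df.columns else None
    return segs, labels


def _looks_like_audacity(path: Path) -> bool:
    first = path.read_text().splitlines()[:1]
    if not first:
        return False
    fields = first[0].split("\t")
    try:
        float(fields[0]), float(fields[1])
        return True
    except (ValueError, IndexError):
        return False


def write_audacity_labels(path, segments: SegmentList, label: str = "snore") -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.t_start_s:.6f}\t{s.t_end_s:.6f}\t{label}\n")


def write_mel_dataset(directory, mels: list[MelSpectrogram]) -> None:
    """NPY matrix + JSON sidecar (clip_id, label, config) per spectrogram."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in mels:
        np.save(directory / f"{m.clip_id}.npy", m.matrix)
        sidecar = {
            "clip_id": m.clip_id,
            "label": m.label,
            "padded": m.padded,
            "config": {
                "n_mels": m.config.n_mels,
                "n_fft": m.config.n_fft,
                "hop_ms": m.config.hop_ms,
                "target_frames": m.config.target_frames,
                "log_scale": m.config.log_scale,
                "mel_variant": m.config.mel_variant,
            },
        }
        (directory / f"{m.clip_id}.json").write_text(json.dumps(sidecar))


def read_mel_dataset(directory) -> list[MelSpectrogram]:
    directory = Path(directory)
    out = []
    for npy in sorted(directory.glob("*.npy")):
        sidecar = npy.with_suffix(".json")
        if not sidecar.exists():
            raise ValidationError(f"missing sidecar for {npy}")
        meta = json.loads(sidecar.read_text())
        out.append(
            MelSpectrogram(
                matrix=np.load(npy),
                clip_id=meta["clip_id"],
                label=meta["label"],
                padded=meta.get("padded", False),
                config=MelConfig(**meta["config"]),
            )
        )
    if not out:
        raise ValidationError(f"no .npy spectrograms found in {directory}")
    return out
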