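"""Training and inference for the snore classifier.

The labelled Mel-spectrogram collection is split 6:2:2 into stratified
train/validation/test subsets, optimized with Adam under cross-entropy,
and the parameters with the best validation loss are returned.  All
randomness (split, shuffling, initialization) flows from the config seed,
so retraining with the same seed is bit-reproducible on one CPU.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .features import MelSpectrogram
from .model import ErbgNet, ModelConfig, build_model
from .nn import Adam, Tensor, cross_entropy

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "stratified_split",
    "train",
    "predict",
    "predict_batch",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    max_epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    early_stop_patience: int = 10
    stop_at_train_acc: float | None = None  # optional convergence early-exit

    def __post_init__(self) -> None:
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValidationError("split ratios must sum to 1")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValidationError("max_epochs and batch_size must be positive")


@dataclass
class TrainedModel:
    """Fitted parameters plus everything needed to reuse them."""

    state: dict
    config: ModelConfig
    label_map: dict  # label -> class index
    history: list = field(default_factory=list)  # per-epoch metric dicts
    norm_mean: float = 0.0
    norm_std: float = 1.0
    split_indices: dict = field(default_factory=dict)
    init_seed: int = 0

    _model: ErbgNet | None = None

    def model(self) -> ErbgNet:
        if self._model is None:
            self._model = build_model(self.config, seed=self.init_seed)
            self._model.load_state_dict(self.state)
        self._model.eval()
        return self._model

    @property
    def inverse_label_map(self) -> dict:
        return {v: k for k, v in self.label_map.items()}


def _dataset_arrays(dataset: list[MelSpectrogram]):
    labels = sorted({m.label for m in dataset})
    if len(labels) < 2:
        raise ValidationError("training requires at least two classes")
    label_map = {lab: i for i, lab in enumerate(labels)}
    x = np.stack([m.matrix for m in dataset]).astype(np.float32)[:, None, :, :]
    y = np.array([label_map[m.label] for m in dataset], dtype=np.int64)
    return x, y, label_map


def stratified_split(y: np.ndarray, ratios, rng: np.random.Generator):
    """Per-class shuffled index split into train/val/test."""
    train_idx, val_idx, test_idx = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = idx.size
        n_tr = int(round(ratios[0] * n))
        n_va = int(round(ratios[1] * n))
        train_idx.append(idx[:n_tr])
        val_idx.append(idx[n_tr : n_tr + n_va])
        test_idx.append(idx[n_tr + n_va :])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(val_idx)),
        np.sort(np.concatenate(test_idx)),
    )


def _evaluate(model: ErbgNet, x: np.ndarray, y: np.ndarray, batch: int):
    model.eval()
    losses, correct = [], 0
    for lo in range(0, x.shape[0], batch):
        xb, yb = x[lo : lo + batch], y[lo : lo + batch]
        logits = model(Tensor(xb))
        losses.append(float(cross_entropy(logits, yb).data) * yb.size)
        correct += int(np.sum(np.argmax(logits.data, axis=1) == yb))
    return sum(losses) / x.shape[0], correct / x.shape[0]


def train(
    model: ErbgNet,
    dataset: list[MelSpectrogram],
    tc: TrainConfig | None = None,
    init_seed: int = 0,
) -> TrainedModel:
    """Fit the classifier on a labelled Mel-spectrogram collection.

    Returns the best-validation-loss checkpoint with per-epoch history
    (epoch, train_acc, train_loss, val_acc, val_loss).
    """
    tc = tc or TrainConfig()
    x, y, label_map = _dataset_arrays(dataset)
    rng = np.random.default_rng(tc.seed)
    tr, va, te = stratified_split(y, tc.split_ratios, rng)
    if tr.size == 0 or va.size == 0:
        raise ValidationError("dataset too small for the requested split")

    mean = float(x[tr].mean())
    std = float(x[tr].std()) or 1.0
    xn = (x - mean) / std

    opt = Adam(model.parameters(), lr=tc.learning_rate)
    best_loss, best_state, patience = np.inf, model.state_dict(), 0
    history = []
    for epoch in range(tc.max_epochs):
        model.train()
        order = rng.permutation(tr)
        ep_loss, ep_correct = 0.0, 0
        for lo in range(0, order.size, tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            xb, yb = xn[idx], y[idx]
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * yb.size
            ep_correct += int(np.sum(np.argmax(logits.data, axis=1) == yb))
        train_loss = ep_loss / order.size
        train_acc = ep_correct / order.size
        val_loss, val_acc = _evaluate(model, xn[va], y[va], tc.batch_size)
        history.append(
            {
                "epoch": epoch + 1,
                "train_acc": train_acc,
                "train_loss": train_loss,
                "val_acc": val_acc,
                "val_loss": val_loss,
            }
        )
        if val_loss < best_loss:
            best_loss, best_state, patience = val_loss, model.state_dict(), 0
        else:
            patience += 1
            if patience >= tc.early_stop_patience:
                break
        if tc.stop_at_train_acc is not None and train_acc >= tc.stop_at_train_acc:
            break

    model.load_state_dict(best_state)
    return TrainedModel(
        state=best_state,
        config=model.config,
        label_map=label_map,
        history=history,
        norm_mean=mean,
        norm_std=std,
        split_indices={"train": tr.tolist(), "val": va.tolist(), "test": te.tolist()},
        init_seed=init_seed,
    )


def predict_batch(trained: TrainedModel, mels: list[MelSpectrogram]):
    """Labels and softmax probabilities for a batch of spectrograms."""
    model = trained.model()
    x = np.stack([m.matrix for m in mels]).astype(np.float32)[:, None, :, :]
    if x.shape[1:] != trained.config.input_shape:
        raise ValidationError(
            f"input shape {x.shape[1:]} != {trained.config.input_shape}"
        )
    xn = (x - trained.norm_mean) / trained.norm_std
    logits = model(Tensor(xn)).data
    logits = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    inv = trained.inverse_label_map
    labels = [inv[int(i)] for i in np.argmax(probs, axis=1)]
    return labels, probs


def predict(trained: TrainedModel, mel: MelSpectrogram):
    """Label and class probabilities for a single spectrogram."""
    labels, probs = predict_batch(trained, [mel])
    return labels[0], probs[0]


def save_checkpoint(path, trained: TrainedModel) -> None:
    """Single-file archive: parameters (npz) + config JSON + label map."""
    meta = {
        "config": {
            "backbone": trained.config.backbone,
            "eca_stages": sorted(trained.config.eca_stages),
            "use_bigru": trained.config.use_bigru,
            "bigru_hidden": trained.config.bigru_hidden,
            "bigru_layers": trained.config.bigru_layers,
            "n_classes": trained.config.n_classes,
            "input_shape": list(trained.config.input_shape),
            "eca": {"gamma": trained.config.eca.gamma, "b": trained.config.eca.b},
        },
        "label_map": trained.label_map,
        "norm_mean": trained.norm_mean,
        "norm_std": trained.norm_std,
        "init_seed": trained.init_seed,
        "history": trained.history,
    }
    buf = BytesIO()
    np.savez(buf, **trained.state)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("state.npz", buf.getvalue())


def load_checkpoint(path) -> TrainedModel:
    from .model import EcaConfig

    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("state.npz") as fh:
            npz = np.load(BytesIO(fh.read()))
            state = {k: npz[k] for k in npz.files}
    cfg = meta["config"]
    config = ModelConfig(
        backbone=cfg["backbone"],
        eca_stages=frozenset(cfg["eca_stages"]),
        use_bigru=cfg["use_bigru"],
        bigru_hidden=cfg["bigru_hidden"],
        bigru_layers=cfg["bigru_layers"],
        n_classes=cfg["n_classes"],
        input_shape=tuple(cfg["input_shape"]),
        eca=EcaConfig(**cfg["eca"]),
    )
    return TrainedModel(
        state=state,
        config=config,
        label_map=meta["label_map"],
        history=meta["history"],
        norm_mean=meta["norm_mean"],
        norm_std=meta["norm_std"],
        init_seed=meta["init_seed"],
    )
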