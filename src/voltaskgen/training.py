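"""Training from scratch, backbone fine-tuning, and head-swap transfer.

The transfer protocol mirrors how the generator is moved to a new cohort:
the output layer's weights are contrast-specific while the backbone encodes
dataset-specific low- and mid-level structure, so adapting to a new dataset
means (i) freezing the output layer and fine-tuning the backbone on the one
contrast the new dataset provides, then (ii) swapping in the pretrained
output-layer slice of any *other* contrast to predict maps that were never
acquired there.  Skipping step (i) is the "no-finetune" path.

All randomness (shuffling, initialization) is driven by explicit seeds;
two runs with identical seeds and configs produce identical loss traces.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .nn.layers import Adam
from .nn.losses import LossConfig, crr_loss_with_grad, reconstructive_loss
from .nn.model import AttentionUNet3D, NetworkSpec

__all__ = [
    "TrainConfig",
    "VolumeDataset",
    "train",
    "finetune_backbone",
    "transfer_predict",
    "extract_heads",
    "clone_model",
    "predict_maps",
]


@dataclass(frozen=True)
class VolumeDataset:
    """Aligned connectomes and contrast maps on a shared grid.

    X : (S, K, nx, ny, nz) voxel-to-ROI connectomes (one per sample; a
        sample may be a subject or a subject-segment used as augmentation).
    Y : (S, C, nx, ny, nz) contrast maps.
    mask : (nx, ny, nz) boolean gray-matter mask used for the loss.
    """

    X: np.ndarray
    Y: np.ndarray
    mask: np.ndarray
    subject_ids: tuple[str, ...]
    contrast_names: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.X, dtype=np.float32)
        Y = np.asarray(self.Y, dtype=np.float32)
        mask = np.asarray(self.mask, dtype=bool)
        if X.ndim != 5 or Y.ndim != 5:
            raise ValueError("X and Y must be 5D (S, channels, nx, ny, nz)")
        if X.shape[0] != Y.shape[0] or X.shape[2:] != Y.shape[2:]:
            raise ValueError("X and Y must agree on samples and grid")
        if mask.shape != X.shape[2:]:
            raise ValueError("mask must match the grid")
        if len(self.subject_ids) != X.shape[0]:
            raise ValueError("one subject id per sample required")
        if len(self.contrast_names) != Y.shape[1]:
            raise ValueError("one contrast name per map channel required")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "contrast_names", tuple(self.contrast_names))

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam throughout).

    ``contrasts`` restricts the loss to a subset of the battery (used for
    single-contrast fine-tuning); ``allow_shared_subject_batches`` can be
    disabled so that segments of the same subject never co-occur in a batch,
    since the contrastive term treats every other batch element as a
    different subject.
    """

    epochs: int = 100
    batch_size: int = 10
    lr: float = 1e-3
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    contrasts: tuple[str, ...] | None = None
    allow_shared_subject_batches: bool = True

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    @classmethod
    def pretrain_defaults(cls, **overrides) -> "TrainConfig":
        """100 epochs, batch 10, Adam lr 1e-3, CR-R with lambda=1, alpha=0.25."""
        return cls(**overrides)

    @classmethod
    def finetune_defaults(cls, **overrides) -> "TrainConfig":
        """50 epochs at a reduced learning rate (1e-4)."""
        overrides.setdefault("epochs", 50)
        overrides.setdefault("lr", 1e-4)
        return cls(**overrides)


def _loss_channels(dataset: VolumeDataset, config: TrainConfig,
                   battery: tuple[str, ...]) -> np.ndarray | None:
    if config.contrasts is None:
        return None
    idx = []
    for name in config.contrasts:
        if name not in battery:
            raise KeyError(f"contrast {name!r} not in model battery {battery}")
        idx.append(battery.index(name))
    return np.asarray(idx)


def _batches(n: int, subject_ids, config: TrainConfig, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    if not config.allow_shared_subject_batches:
        # greedy round-robin so each batch holds distinct subjects
        pools: dict[str, list[int]] = {}
        for i in order:
            pools.setdefault(subject_ids[i], []).append(int(i))
        interleaved: list[int] = []
        while pools:
            for sid in list(pools):
                interleaved.append(pools[sid].pop(0))
                if not pools[sid]:
                    del pools[sid]
        order = np.asarray(interleaved)
    return [order[i : i + config.batch_size]
            for i in range(0, n, config.batch_size)]


def _val_mse(model: AttentionUNet3D, val_set: VolumeDataset,
             channels, batch: int = 8) -> float:
    total, count = 0.0, 0
    for i in range(0, len(val_set), batch):
        pred = model.predict(val_set.X[i : i + batch])
        n = pred.shape[0]
        total += n * reconstructive_loss(pred, val_set.Y[i : i + batch],
                                         val_set.mask, channels=channels)
        count += n
    return total / count


def _run_training(model, train_set, val_set, config, params):
    """Shared loop for pretraining and fine-tuning."""
    if len(train_set) == 0 or (val_set is not None and len(val_set) == 0):
        raise ValueError("empty split")
    battery = getattr(model, "contrast_names", None) or train_set.contrast_names
    model.contrast_names = tuple(battery)
    channels = _loss_channels(train_set, config, tuple(battery))

    rng = np.random.default_rng(config.seed)
    opt = Adam(params, lr=config.lr)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None, -1)

    for epoch in range(config.epochs):
        losses = []
        for batch in _batches(len(train_set), train_set.subject_ids, config, rng):
            pred = model.forward(train_set.X[batch], train=True)
            loss, grad, _ = crr_loss_with_grad(
                pred, train_set.Y[batch], train_set.mask, config.loss,
                channels=channels)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {batch.tolist()}")
            opt.zero_grad()
            model.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_set is not None:
            v = _val_mse(model, val_set, channels)
            history["val_loss"].append(v)
            if v < best[0]:
                best = (v, model.state_dict(), epoch)

    if val_set is not None and best[1] is not None:
        model.load_state_dict(best[1])
        history["best_epoch"] = best[2]
    return model, history


def train(model: AttentionUNet3D, train_set: VolumeDataset,
          val_set: VolumeDataset | None, config: TrainConfig):
    """Train all parameters by minimizing the CR-R loss over in-mask voxels.

    Returns ``(model, history)`` where history records per-epoch train CR-R
    loss and validation masked MSE; the parameters of the epoch with the
    lowest validation MSE are restored at the end.
    """
    model.contrast_names = train_set.contrast_names
    return _run_training(model, train_set, val_set, config, model.params())


def finetune_backbone(model: AttentionUNet3D, dataset: VolumeDataset,
                      config: TrainConfig | None = None,
                      val_set: VolumeDataset | None = None):
    """Fine-tune the backbone with a frozen output layer.

    *dataset* must supply exactly one contrast present in the model's
    battery; the loss is computed only on that contrast's channel and the
    output-layer parameters are bit-identical before and after (they are
    excluded from the optimizer and their gradients never applied).
    """
    if len(dataset.contrast_names) != 1:
        raise ValueError("fine-tuning dataset must supply exactly one contrast")
    contrast = dataset.contrast_names[0]
    battery = getattr(model, "contrast_names", None)
    if battery is None:
        raise ValueError("model has no contrast battery; train it first")
    if contrast not in battery:
        raise KeyError(f"contrast {contrast!r} not in model battery {battery}")
    if config is None:
        config = TrainConfig.finetune_defaults()

    channel = battery.index(contrast)
    # view the single-contrast maps as the matching channel of the battery
    Y = np.zeros((len(dataset), len(battery)) + dataset.Y.shape[2:],
                 dtype=np.float32)
    Y[:, channel] = dataset.Y[:, 0]
    full = VolumeDataset(dataset.X, Y, dataset.mask, dataset.subject_ids,
                         tuple(battery))
    if val_set is not None and len(val_set.contrast_names) == 1:
        Yv = np.zeros((len(val_set), len(battery)) + val_set.Y.shape[2:],
                      dtype=np.float32)
        Yv[:, channel] = val_set.Y[:, 0]
        val_set = VolumeDataset(val_set.X, Yv, val_set.mask,
                                val_set.subject_ids, tuple(battery))
    config = replace(config, contrasts=(contrast,))
    return _run_training(model, full, val_set, config, model.backbone_params())


def extract_heads(model: AttentionUNet3D) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-contrast copies of the output layer's (weight, bias) slices."""
    battery = getattr(model, "contrast_names", None)
    if battery is None:
        battery = tuple(f"contrast_{i}" for i in range(model.spec.out_channels))
    return {name: model.get_head_slice(i) for i, name in enumerate(battery)}


def clone_model(model: AttentionUNet3D) -> AttentionUNet3D:
    clone = AttentionUNet3D(model.spec, seed=0)
    clone.load_state_dict(model.state_dict())
    if hasattr(model, "contrast_names"):
        clone.contrast_names = model.contrast_names
    return clone


def transfer_predict(model: AttentionUNet3D,
                     pretrained_heads: dict[str, tuple[np.ndarray, np.ndarray]],
                     target_contrast: str, connectomes: np.ndarray,
                     batch: int = 8) -> np.ndarray:
    """Predict *target_contrast* maps with a swapped pretrained head.

    Uses the (fine-tuned) backbone of *model* and the pretrained output-layer
    slice for the target contrast.  Passing the unmodified pretrained model
    gives the "no-finetune" path.  Returns maps of shape (S, nx, ny, nz).
    """
    if target_contrast not in pretrained_heads:
        raise KeyError(
            f"contrast {target_contrast!r} not among pretrained heads "
            f"{sorted(pretrained_heads)}")
    battery = getattr(model, "contrast_names", None)
    if battery is None or target_contrast not in battery:
        raise KeyError(
            f"contrast {target_contrast!r} not in model battery {battery}")
    channel = battery.index(target_contrast)
    w, b = pretrained_heads[target_contrast]
    swapped = clone_model(model)
    swapped.set_head_slice(channel, w, b)
    return predict_maps(swapped, connectomes, channel=channel, batch=batch)


def predict_maps(model: AttentionUNet3D, connectomes: np.ndarray,
                 channel: int | None = None, batch: int = 8) -> np.ndarray:
    """Evaluation-mode predictions for a stack of connectomes.

    Returns (S, C, nx, ny, nz), or (S, nx, ny, nz) if *channel* is given.
    """
    connectomes = np.asarray(connectomes, dtype=np.float32)
    out = []
    for i in range(0, connectomes.shape[0], batch):
        pred = model.predict(connectomes[i : i + batch])
        out.append(pred if channel is None else pred[:, channel])
    return np.concatenate(out, axis=0)
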