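"""Training, freeze/fine-tune contracts, and head-swap transfer orderings."""

import numpy as np
import pytest

from voltaskgen.metrics import (
    diagonality_index,
    reconstruction_correlation,
    similarity_matrix,
)
from voltaskgen.nn.model import AttentionUNet3D, NetworkSpec
from voltaskgen.training import (
    TrainConfig,
    VolumeDataset,
    clone_model,
    extract_heads,
    finetune_backbone,
    train,
    transfer_predict,
)

SPEC = NetworkSpec(in_channels=2, out_channels=2, depth=1, base_channels=4)


def _toy_dataset(n=6, seed=0, c=2, names=("c0", "c1")):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2, 8, 8, 8)).astype(np.float32)
    # targets depend on the inputs so there is something to learn
    Y = np.stack([X.mean(axis=1) + 0.1 * rng.normal(size=(n, 8, 8, 8))
                  for _ in range(c)], axis=1).astype(np.float32)
    mask = np.ones((8, 8, 8), bool)
    ids = tuple(f"s{i}" for i in range(n))
    return VolumeDataset(X, Y, mask, ids, names)


def test_identical_seeds_give_identical_loss_traces():
    ds = _toy_dataset()
    cfg = TrainConfig(epochs=3, batch_size=3, seed=42)
    _, h1 = train(AttentionUNet3D(SPEC, seed=1), ds, None, cfg)
    _, h2 = train(AttentionUNet3D(SPEC, seed=1), ds, None, cfg)
    assert h1["train_loss"] == h2["train_loss"]


def test_training_reduces_loss(study):
    """Final train loss on the study cohort sits strictly below epoch 1's."""
    hist = study["history"]
    assert hist["train_loss"][-1] < hist["train_loss"][0]
    assert hist["val_loss"][int(hist["best_epoch"])] == min(hist["val_loss"])


def test_single_sample_overfit_capacity():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(1, 2, 8, 8, 8)).astype(np.float32)
    Y = np.stack([X.mean(axis=1), X[:, 0] - X[:, 1]], axis=1).astype(np.float32)
    ds = VolumeDataset(X, Y, np.ones((8, 8, 8), bool), ("s0",), ("c0", "c1"))
    cfg = TrainConfig(epochs=300, batch_size=1, lr=1e-2, seed=0)
    wide = NetworkSpec(in_channels=2, out_channels=2, depth=1, base_channels=8)
    _, hist = train(AttentionUNet3D(wide, seed=2), ds, None, cfg)
    assert hist["train_loss"][-1] < 1e-2 * hist["train_loss"][0]


def test_empty_split_rejected():
    ds = _toy_dataset()
    empty = VolumeDataset(ds.X[:0], ds.Y[:0], ds.mask, (), ds.contrast_names)
    with pytest.raises(ValueError, match="empty"):
        train(AttentionUNet3D(SPEC, seed=1), empty, None,
              TrainConfig(epochs=1))


def test_finetune_freezes_output_layer_bitwise():
    ds = _toy_dataset()
    model, _ = train(AttentionUNet3D(SPEC, seed=1), ds, None,
                     TrainConfig(epochs=2, batch_size=3, seed=0))
    head_before = {k: v.copy() for k, v in model.head_state().items()}
    backbone_before = model.backbone_state()
    single = VolumeDataset(ds.X, ds.Y[:, 0:1], ds.mask, ds.subject_ids, ("c0",))
    model, _ = finetune_backbone(model, single,
                                 TrainConfig(epochs=2, batch_size=3, seed=1))
    for k, v in model.head_state().items():
        assert np.array_equal(v, head_before[k]), k          # frozen, bit-identical
    changed = any(not np.array_equal(v, backbone_before[k])
                  for k, v in model.backbone_state().items()
                  if not k.endswith(("running_mean", "running_var")))
    assert changed                                            # backbone moved


def test_finetune_with_zero_learning_rate_changes_nothing():
    ds = _toy_dataset()
    model, _ = train(AttentionUNet3D(SPEC, seed=1), ds, None,
                     TrainConfig(epochs=1, batch_size=3, seed=0))
    before = model.state_dict()
    single = VolumeDataset(ds.X, ds.Y[:, 0:1], ds.mask, ds.subject_ids, ("c0",))
    model, _ = finetune_backbone(
        model, single, TrainConfig(epochs=2, batch_size=3, lr=0.0, seed=1))
    after = model.state_dict()
    for k in before:
        if k.endswith(("running_mean", "running_var")):
            continue  # batch-norm statistics track data regardless of lr
        assert np.array_equal(before[k], after[k]), k


def test_finetune_requires_known_single_contrast():
    ds = _toy_dataset()
    model, _ = train(AttentionUNet3D(SPEC, seed=1), ds, None,
                     TrainConfig(epochs=1, batch_size=3, seed=0))
    stranger = VolumeDataset(ds.X, ds.Y[:, 0:1], ds.mask, ds.subject_ids,
                             ("not-in-battery",))
    with pytest.raises(KeyError):
        finetune_backbone(model, stranger, TrainConfig(epochs=1))
    both = VolumeDataset(ds.X, ds.Y, ds.mask, ds.subject_ids, ds.contrast_names)
    with pytest.raises(ValueError, match="exactly one"):
        finetune_backbone(model, both, TrainConfig(epochs=1))


def test_headswap_with_unchanged_backbone_is_identity():
    ds = _toy_dataset()
    model, _ = train(AttentionUNet3D(SPEC, seed=1), ds, None,
                     TrainConfig(epochs=1, batch_size=3, seed=0))
    heads = extract_heads(model)
    direct = model.predict(ds.X)[:, 0]  # same batching as the transfer path
    swapped = transfer_predict(model, heads, "c0", ds.X)
    assert np.array_equal(direct, swapped)


def test_transfer_requires_known_head():
    ds = _toy_dataset()
    model, _ = train(AttentionUNet3D(SPEC, seed=1), ds, None,
                     TrainConfig(epochs=1, batch_size=3, seed=0))
    heads = extract_heads(model)
    with pytest.raises(KeyError):
        transfer_predict(model, heads, "c9", ds.X)
    with pytest.raises(KeyError):
        transfer_predict(model, {"c9": heads["c0"]}, "c9", ds.X)


def test_gradients_do_not_leak_into_frozen_head():
    """After a fine-tune step the optimizer never touched head parameters."""
    ds = _toy_dataset()
    model, _ = train(AttentionUNet3D(SPEC, seed=1), ds, None,
                     TrainConfig(epochs=1, batch_size=3, seed=0))
    single = VolumeDataset(ds.X, ds.Y[:, 0:1], ds.mask, ds.subject_ids, ("c0",))
    ids_before = [id(p.data) for p in model.head_params()]
    head_before = {k: v.copy() for k, v in model.head_state().items()}
    model, _ = finetune_backbone(model, single,
                                 TrainConfig(epochs=3, batch_size=2, seed=2))
    assert [id(p.data) for p in model.head_params()] == ids_before
    for k, v in model.head_state().items():
        assert np.array_equal(v, head_before[k])


# -- end-to-end transfer orderings on the shifted synthetic cohort ----------

def test_no_finetune_degrades_under_distribution_shift(study, transfer_study):
    """Reconstruction on the shifted cohort falls below in-distribution."""
    mask = study["mask"]
    r_in = np.mean(reconstruction_correlation(
        study["pred_net"][:, 0], study["actual"][:, 0], mask))
    r_shift = np.mean(reconstruction_correlation(
        transfer_study["preds"][("no_finetune", "c0")],
        transfer_study["actual"][:, 0], mask))
    assert r_shift < r_in


def test_backbone_finetuning_recovers_reconstruction(transfer_study):
    """Fine-tuning the backbone on the available contrast recovers signal."""
    mask = transfer_study["cohort"].grid.mask
    actual = transfer_study["actual"]
    r_nf = np.mean(reconstruction_correlation(
        transfer_study["preds"][("no_finetune", "c0")], actual[:, 0], mask))
    r_ft = np.mean(reconstruction_correlation(
        transfer_study["preds"][("finetuned", "c0")], actual[:, 0], mask))
    assert r_ft > r_nf
    assert r_ft > 0.5


def test_finetuning_improves_heldout_discriminability(transfer_study):
    """Diagonality of the head-swapped, never-fine-tuned contrast improves."""
    mask = transfer_study["cohort"].grid.mask
    actual = transfer_study["actual"]
    di_nf = diagonality_index(similarity_matrix(
        transfer_study["preds"][("no_finetune", "c1")], actual[:, 1], mask))
    di_ft = diagonality_index(similarity_matrix(
        transfer_study["preds"][("finetuned", "c1")], actual[:, 1], mask))
    assert di_ft > di_nf


def test_wrong_head_underperforms_matched_head(transfer_study):
    """Swapping in another contrast's head breaks target reconstruction."""
    mask = transfer_study["cohort"].grid.mask
    actual = transfer_study["actual"]
    r_matched = np.mean(reconstruction_correlation(
        transfer_study["preds"][("finetuned", "c1")], actual[:, 1], mask))
    r_wrong = np.mean(reconstruction_correlation(
        transfer_study["preds"][("finetuned", "c2")], actual[:, 1], mask))
    assert r_wrong < r_matched
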