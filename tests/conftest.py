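"""Shared fixtures: small grids and the seeded end-to-end study cohorts."""

from dataclasses import replace

import numpy as np
import pytest

from voltaskgen.baselines import (
    fit_linear_roi_baseline,
    group_average_predictor,
    predict_linear_roi,
)
from voltaskgen.nn.model import AttentionUNet3D, NetworkSpec
from voltaskgen.synthcohort import (
    SyntheticCohortSpec,
    generate_cohort,
    generate_transfer_cohort,
)
from voltaskgen.training import (
    TrainConfig,
    VolumeDataset,
    clone_model,
    extract_heads,
    finetune_backbone,
    train,
    transfer_predict,
)
from voltaskgen.volio import MaskedGrid

# the main study split: 20 train / 4 validation / 8 test out of 32 subjects
TRAIN, VAL, TEST = slice(0, 20), slice(20, 24), slice(24, 32)


@pytest.fixture
def tiny_grid():
    """4x4x4 grid, all voxels in-mask, 2 mm."""
    return MaskedGrid(dims=(4, 4, 4), affine=np.diag([2.0, 2.0, 2.0, 1.0]),
                      mask=np.ones((4, 4, 4), bool))


@pytest.fixture(scope="session")
def linear_cohort():
    """Low-noise cohort with a linear rest-to-task mapping (well-specified).

    Task noise is kept small so ordinary least squares stays in the regime
    where its theoretical advantage over the unconditional group mean is
    visible at a 9-subject training-set size.
    """
    spec = SyntheticCohortSpec(n_subjects=12, n_timepoints=200,
                               rest_noise_sd=0.3, task_noise_sd=0.02,
                               nonlinear=False, seed=21)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def study():
    """Nonlinear cohort + trained network + baselines on a held-out split.

    This is the package's main synthetic recovery experiment: 32 subjects
    on a 12^3 grid (K=6, C=3), network trained for 60 epochs, the per-ROI
    linear baseline fit on train+validation, and the group-average
    predictor; everything evaluated on the 8 test subjects.
    """
    spec = SyntheticCohortSpec(nonlinear=True, seed=7)
    cohort = generate_cohort(spec)
    mask = cohort.grid.mask
    names = tuple(f"c{i}" for i in range(spec.n_contrasts))
    ids = cohort.subject_ids
    X = cohort.connectomes.astype(np.float32)
    Y = cohort.maps.astype(np.float32)

    net = AttentionUNet3D(
        NetworkSpec(in_channels=spec.n_components,
                    out_channels=spec.n_contrasts,
                    depth=2, base_channels=8), seed=3)
    net, history = train(
        net,
        VolumeDataset(X[TRAIN], Y[TRAIN], mask, ids[TRAIN], names),
        VolumeDataset(X[VAL], Y[VAL], mask, ids[VAL], names),
        TrainConfig(epochs=60, batch_size=8, seed=11))

    linear = fit_linear_roi_baseline(cohort.connectomes[:24],
                                     cohort.maps[:24], cohort.atlas)
    pred_net = np.stack([net.predict(X[i]) for i in range(24, 32)])
    pred_lin = np.stack([predict_linear_roi(linear, cohort.connectomes[i],
                                            cohort.atlas)
                         for i in range(24, 32)])
    group_avg = group_average_predictor(cohort.maps[:24])
    pred_ga = np.tile(group_avg[None], (8, 1, 1, 1, 1))
    return {
        "spec": spec, "cohort": cohort, "mask": mask, "names": names,
        "net": net, "history": history, "linear": linear,
        "pred_net": pred_net, "pred_lin": pred_lin, "pred_ga": pred_ga,
        "actual": cohort.maps[TEST],
    }


@pytest.fixture(scope="session")
def transfer_study(study):
    """Shifted second cohort + no-finetune and fine-tuned-backbone paths.

    The backbone is fine-tuned on contrast c0 only (frozen output layer);
    c1 is the held-out contrast reached by head swap.
    """
    spec = study["spec"]
    base = study["cohort"]
    mask = study["mask"]
    net = study["net"]
    heads = extract_heads(net)

    tspec = replace(spec, seed=99, transfer_shift=0.5)
    tcoh = generate_transfer_cohort(tspec, base)
    Xt = tcoh.connectomes.astype(np.float32)
    Yt = tcoh.maps.astype(np.float32)

    finetuned = clone_model(net)
    finetuned, _ = finetune_backbone(
        finetuned,
        VolumeDataset(Xt[TRAIN], Yt[TRAIN, 0:1], mask,
                      tcoh.subject_ids[TRAIN], ("c0",)),
        TrainConfig.finetune_defaults(epochs=60, lr=5e-4, seed=5),
        val_set=VolumeDataset(Xt[VAL], Yt[VAL, 0:1], mask,
                              tcoh.subject_ids[VAL], ("c0",)))

    preds = {}
    for label, model in [("no_finetune", net), ("finetuned", finetuned)]:
        for contrast in ("c0", "c1", "c2"):
            preds[(label, contrast)] = transfer_predict(
                model, heads, contrast, Xt[TEST])
    return {
        "cohort": tcoh, "mask": mask, "net": net, "finetuned": finetuned,
        "heads": heads, "preds": preds, "actual": Yt[TEST],
        "X_test": Xt[TEST],
    }
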