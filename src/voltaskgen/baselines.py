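"""Comparison predictors: group average, per-ROI linear model, retest scans.

* The group-average predictor emits the voxelwise mean of the training maps
  for every test subject — it captures exactly the features shared across
  individuals and carries zero inter-individual information.
* The per-ROI linear model regresses, within each ROI, every voxel's
  contrast value on that voxel's K connectome channels (ordinary least
  squares, voxels of the ROI as samples, intercept included by default).
  Weights are fit per subject and then averaged across training subjects;
  prediction applies the averaged weights ROI-wise.  The bookkeeping counts
  one fit per (ROI, subject, contrast).
* Retest scans: a second task session treated as the "prediction" of the
  first, the empirical reliability reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import IcaAtlas

__all__ = [
    "LinearRoiModel",
    "group_average_predictor",
    "fit_linear_roi_baseline",
    "predict_linear_roi",
    "retest_reference",
    "planned_fit_count",
]


def planned_fit_count(n_rois: int, n_subjects: int, n_contrasts: int) -> int:
    """Number of per-(ROI, subject, contrast) OLS fits the baseline performs."""
    return n_rois * n_subjects * n_contrasts


def group_average_predictor(train_maps: np.ndarray) -> np.ndarray:
    """Voxelwise mean over training subjects, shape = one map per contrast.

    ``train_maps`` is (S, ...) with any trailing map shape; the same
    prediction is emitted for every test subject.
    """
    train_maps = np.asarray(train_maps, dtype=np.float64)
    if train_maps.shape[0] < 1:
        raise ValueError("need at least one training map")
    return train_maps.mean(axis=0)


@dataclass(frozen=True)
class LinearRoiModel:
    """Averaged per-ROI OLS weights: shape (R, C, K + intercept)."""

    weights: np.ndarray            # (R, C, K [+ 1])
    include_intercept: bool
    n_fits: int                    # fits performed during training
    n_components: int              # K connectome channels

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")


def _roi_voxel_lists(atlas: IcaAtlas) -> list[np.ndarray]:
    labels = atlas.masked_labels()
    return [np.flatnonzero(labels == k)
            for k in range(1, atlas.n_components + 1)]


def fit_linear_roi_baseline(connectomes: np.ndarray, maps: np.ndarray,
                            atlas: IcaAtlas,
                            include_intercept: bool = True) -> LinearRoiModel:
    """Fit the per-ROI linear baseline.

    connectomes : (S, K, nx, ny, nz) — one connectome per subject (mean over
        segments upstream if segments were used).
    maps : (S, C, nx, ny, nz) target contrast maps.

    For every (subject, ROI): OLS from each in-mask voxel's K connectome
    values (+ intercept) to its contrast values, all C contrasts solved
    against the same design.  Rank-deficient ROI designs fall back to the
    minimum-norm least-squares solution with a warning.  Weights are then
    averaged over subjects.
    """
    X = np.asarray(connectomes, dtype=np.float64)
    Y = np.asarray(maps, dtype=np.float64)
    if X.ndim != 5 or Y.ndim != 5 or X.shape[0] != Y.shape[0]:
        raise ValueError("connectomes and maps must be (S, channels, grid) "
                         "with equal subject counts")
    S, K = X.shape[0], X.shape[1]
    C = Y.shape[1]
    mask = atlas.grid.mask
    Xm = X[:, :, mask]  # (S, K, n_mask)
    Ym = Y[:, :, mask]  # (S, C, n_mask)
    rois = _roi_voxel_lists(atlas)
    R = len(rois)
    P = K + (1 if include_intercept else 0)

    weights = np.zeros((R, C, P))
    rank_warned = False
    for r, vox in enumerate(rois):
        for s in range(S):
            design = Xm[s][:, vox].T  # (n_vox, K)
            if include_intercept:
                design = np.column_stack([design, np.ones(len(vox))])
            target = Ym[s][:, vox].T  # (n_vox, C)
            sol, _, rank, _ = np.linalg.lstsq(design, target)
            if rank < design.shape[1] and not rank_warned:
                warnings.warn(
                    f"rank-deficient design in ROI {r + 1} "
                    "(minimum-norm solution used)", RuntimeWarning)
                rank_warned = True
            weights[r] += sol.T  # (C, P)
    weights /= S
    return LinearRoiModel(weights=weights, include_intercept=include_intercept,
                          n_fits=planned_fit_count(R, S, C), n_components=K)


def predict_linear_roi(model: LinearRoiModel, connectome: np.ndarray,
                       atlas: IcaAtlas) -> np.ndarray:
    """Predict contrast maps for one subject, shape (C, nx, ny, nz).

    Voxel value = averaged ROI weights dotted with the voxel's connectome
    features (+ intercept); zeros outside the mask.
    """
    X = np.asarray(connectome, dtype=np.float64)
    if X.shape[0] != model.n_components:
        raise ValueError(
            f"connectome has {X.shape[0]} channels, model expects "
            f"{model.n_components}")
    mask = atlas.grid.mask
    rois = _roi_voxel_lists(atlas)
    if len(rois) != model.weights.shape[0]:
        raise ValueError("atlas partition does not match the fitted model")
    Xm = X[:, mask]  # (K, n_mask)
    C = model.weights.shape[1]
    out = np.zeros((C, mask.sum()))
    for r, vox in enumerate(rois):
        feats = Xm[:, vox].T  # (n_vox, K)
        if model.include_intercept:
            feats = np.column_stack([feats, np.ones(len(vox))])
        out[:, vox] = (feats @ model.weights[r].T).T  # (C, n_vox)
    full = np.zeros((C,) + mask.shape)
    full[:, mask] = out
    return full


def retest_reference(maps_session1: np.ndarray, maps_session2: np.ndarray,
                     subject_ids1=None, subject_ids2=None):
    """Treat session-2 maps as the "prediction" of session-1 maps.

    Returns ``(preds, actuals)`` ready for the metrics module.  Subject
    lists, when given, must match exactly (same order).
    """
    s1 = np.asarray(maps_session1, dtype=np.float64)
    s2 = np.asarray(maps_session2, dtype=np.float64)
    if s1.shape != s2.shape:
        raise ValueError("sessions must hold the same subjects and contrast")
    if subject_ids1 is not None or subject_ids2 is not None:
        if tuple(subject_ids1) != tuple(subject_ids2):
            raise ValueError("session subject lists differ")
    return s2, s1
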