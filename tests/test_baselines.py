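"""Group-average, per-ROI linear, and retest baselines."""

import numpy as np
import pytest

from voltaskgen.baselines import (
    LinearRoiModel,
    fit_linear_roi_baseline,
    group_average_predictor,
    planned_fit_count,
    predict_linear_roi,
    retest_reference,
)
from voltaskgen.connectome import IcaAtlas
from voltaskgen.metrics import (
    diagonality_index,
    reconstruction_correlation,
    similarity_matrix,
)
from voltaskgen.volio import MaskedGrid


def _one_roi_atlas(shape=(5, 1, 1)):
    grid = MaskedGrid(dims=shape, affine=np.eye(4), mask=np.ones(shape, bool))
    return IcaAtlas(grid=grid, mode="hard-labels",
                    labels=np.ones(shape, np.int64))


# -- group average ----------------------------------------------------------

def test_group_average_of_opposite_maps_is_zero():
    m = np.random.default_rng(0).normal(size=(1, 4, 4, 4))
    assert np.allclose(group_average_predictor(np.stack([m, -m])), 0.0)


def test_group_average_of_single_subject_is_that_subject():
    m = np.random.default_rng(1).normal(size=(1, 2, 4, 4, 4))
    assert np.array_equal(group_average_predictor(m), m[0])


def test_group_average_diagonality_is_exactly_zero():
    """Identical rows in the similarity matrix cancel the index exactly."""
    rng = np.random.default_rng(2)
    actual = rng.normal(size=(6, 4, 4, 4))
    mask = np.ones((4, 4, 4), bool)
    ga = group_average_predictor(actual)
    preds = np.tile(ga[None], (6, 1, 1, 1))
    S = similarity_matrix(preds, actual, mask)
    assert diagonality_index(S, normalized=False) == pytest.approx(0.0, abs=1e-12)
    assert diagonality_index(S, normalized=True) == pytest.approx(0.0, abs=1e-12)


# -- linear per-ROI model ---------------------------------------------------

def test_fit_count_bookkeeping():
    assert planned_fit_count(50, 919, 47) == 2_159_650
    atlas = _one_roi_atlas()
    rng = np.random.default_rng(3)
    X = rng.normal(size=(3, 2, 5, 1, 1))
    Y = rng.normal(size=(3, 4, 5, 1, 1))
    model = fit_linear_roi_baseline(X, Y, atlas)
    assert model.n_fits == planned_fit_count(1, 3, 4) == 12


def test_weights_match_hand_solved_normal_equations():
    """1 ROI, 2 features, 5 voxels: compare with (X'X)^-1 X'y directly."""
    atlas = _one_roi_atlas()
    rng = np.random.default_rng(4)
    X = rng.normal(size=(1, 2, 5, 1, 1))
    Y = rng.normal(size=(1, 1, 5, 1, 1))
    model = fit_linear_roi_baseline(X, Y, atlas)
    design = np.column_stack([X[0, 0].ravel(), X[0, 1].ravel(), np.ones(5)])
    beta = np.linalg.solve(design.T @ design, design.T @ Y[0, 0].ravel())
    assert np.allclose(model.weights[0, 0], beta, atol=1e-10)


def test_ols_reproduces_exactly_linear_map():
    """A map that is a linear function of the connectome is recovered exactly."""
    atlas = _one_roi_atlas(shape=(8, 1, 1))
    rng = np.random.default_rng(5)
    X = rng.normal(size=(1, 3, 8, 1, 1))
    w, b = np.array([0.5, -1.2, 2.0]), 0.7
    Y = (np.tensordot(w, X[0], axes=(0, 0)) + b)[None, None]
    model = fit_linear_roi_baseline(X, Y, atlas)
    pred = predict_linear_roi(model, X[0], atlas)
    assert np.allclose(pred, Y[0], atol=1e-10)


def test_zero_connectome_predicts_intercepts():
    atlas = _one_roi_atlas()
    rng = np.random.default_rng(6)
    X = rng.normal(size=(2, 2, 5, 1, 1))
    Y = rng.normal(size=(2, 1, 5, 1, 1))
    model = fit_linear_roi_baseline(X, Y, atlas)
    pred = predict_linear_roi(model, np.zeros((2, 5, 1, 1)), atlas)
    assert np.allclose(pred[0], model.weights[0, 0, -1])


def test_duplicating_the_cohort_leaves_weights_unchanged():
    atlas = _one_roi_atlas()
    rng = np.random.default_rng(7)
    X = rng.normal(size=(3, 2, 5, 1, 1))
    Y = rng.normal(size=(3, 2, 5, 1, 1))
    once = fit_linear_roi_baseline(X, Y, atlas)
    twice = fit_linear_roi_baseline(np.concatenate([X, X]),
                                    np.concatenate([Y, Y]), atlas)
    assert np.allclose(once.weights, twice.weights, atol=1e-12)


def test_intercept_only_model_degenerates_to_roi_mean():
    """With zero connectome channels the fit reduces to the per-ROI mean."""
    atlas = _one_roi_atlas()
    rng = np.random.default_rng(8)
    X = np.zeros((2, 0, 5, 1, 1))
    Y = rng.normal(size=(2, 1, 5, 1, 1))
    model = fit_linear_roi_baseline(X, Y, atlas)
    pred = predict_linear_roi(model, np.zeros((0, 5, 1, 1)), atlas)
    assert np.allclose(pred, Y.mean(axis=(0, 2, 3, 4)), atol=1e-10)


def test_linear_baseline_is_exact_on_noiseless_linear_cohort():
    """With zero noise and a linear generative map, held-out r > 0.999."""
    from voltaskgen.synthcohort import SyntheticCohortSpec, generate_cohort
    spec = SyntheticCohortSpec(n_subjects=8, n_timepoints=80,
                               rest_noise_sd=0.0, task_noise_sd=0.0,
                               nonlinear=False, seed=13)
    coh = generate_cohort(spec)
    model = fit_linear_roi_baseline(coh.connectomes[:6], coh.maps[:6], coh.atlas)
    mask = coh.grid.mask
    for i in (6, 7):  # held-out subjects
        pred = predict_linear_roi(model, coh.connectomes[i], coh.atlas)
        r = reconstruction_correlation(pred, coh.maps[i], mask)
        assert np.all(np.asarray(r) > 0.999)


def test_linear_baseline_beats_group_average_on_linear_cohort(linear_cohort):
    coh = linear_cohort
    mask = coh.grid.mask
    model = fit_linear_roi_baseline(coh.connectomes[:9], coh.maps[:9], coh.atlas)
    ga = group_average_predictor(coh.maps[:9])
    r_lin, r_ga = [], []
    for i in (9, 10, 11):
        pred = predict_linear_roi(model, coh.connectomes[i], coh.atlas)
        r_lin.append(np.mean(reconstruction_correlation(pred, coh.maps[i], mask)))
        r_ga.append(np.mean(reconstruction_correlation(ga, coh.maps[i], mask)))
    assert np.mean(r_lin) >= np.mean(r_ga)


def test_channel_count_mismatch_rejected():
    atlas = _one_roi_atlas()
    model = LinearRoiModel(weights=np.zeros((1, 1, 3)), include_intercept=True,
                           n_fits=1, n_components=2)
    with pytest.raises(ValueError):
        predict_linear_roi(model, np.zeros((4, 5, 1, 1)), atlas)


# -- retest reference -------------------------------------------------------

def test_identical_retest_sessions_give_perfect_reconstruction():
    rng = np.random.default_rng(9)
    maps = rng.normal(size=(4, 4, 4, 4))
    mask = np.ones((4, 4, 4), bool)
    preds, actuals = retest_reference(maps, maps.copy())
    r = reconstruction_correlation(preds, actuals, mask)
    assert np.allclose(r, 1.0)


def test_independent_noise_sessions_decorrelate():
    rng = np.random.default_rng(10)
    mask = np.ones((8, 8, 8), bool)
    s1 = rng.normal(size=(10, 8, 8, 8))
    s2 = rng.normal(size=(10, 8, 8, 8))
    preds, actuals = retest_reference(s1, s2)
    r = reconstruction_correlation(preds, actuals, mask)
    assert abs(np.mean(r)) < 3.0 / np.sqrt(mask.sum())


def test_noisy_retest_has_positive_diagonality():
    rng = np.random.default_rng(11)
    mask = np.ones((6, 6, 6), bool)
    s1 = rng.normal(size=(8, 6, 6, 6))
    s2 = s1 + 0.3 * rng.normal(size=s1.shape)
    preds, actuals = retest_reference(s1, s2)
    S = similarity_matrix(preds, actuals, mask)
    assert diagonality_index(S) > 0.0


def test_session_subject_mismatch_rejected():
    maps = np.zeros((2, 2, 2, 2))
    with pytest.raises(ValueError):
        retest_reference(maps, maps, ["a", "b"], ["b", "a"])
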