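"""Connectome construction against brute-force Pearson oracles."""

import numpy as np
import pytest
from scipy import stats

from voltaskgen.connectome import (
    BoldTimeSeries,
    IcaAtlas,
    roi_signals,
    roi_to_roi_connectome,
    split_timeseries,
    upper_triangle,
    voxel_to_roi_connectome,
)
from voltaskgen.volio import MaskedGrid


def _grid(shape=(2, 2, 2)):
    return MaskedGrid(dims=shape, affine=np.eye(4), mask=np.ones(shape, bool))


def _series(values, grid):
    return BoldTimeSeries(subject_id="s", values=np.asarray(values, float),
                          grid=grid)


# -- segmentation -----------------------------------------------------------

@pytest.mark.parametrize("T,seg,expected", [
    (4800, 600, 8),   # four 1200-timepoint runs split into eight parts
    (10, 5, 2),
    (13, 5, 2),       # 3 trailing timepoints dropped
])
def test_segment_counts(T, seg, expected):
    grid = _grid()
    ts = _series(np.tile(np.arange(T, dtype=float), (grid.n_mask, 1)), grid)
    parts = split_timeseries(ts, seg)
    assert len(parts) == expected
    # contiguous, order-preserving, remainder dropped
    for i, part in enumerate(parts):
        assert np.array_equal(part.values[0], np.arange(i * seg, (i + 1) * seg))


def test_segment_longer_than_series_rejected():
    grid = _grid()
    ts = _series(np.zeros((grid.n_mask, 10)) + np.arange(10), grid)
    with pytest.raises(ValueError, match="no full segment"):
        split_timeseries(ts, 11)
    with pytest.raises(ValueError):
        split_timeseries(ts, 1)


# -- ROI signals ------------------------------------------------------------

def test_single_voxel_roi_signal_equals_voxel_series():
    grid = _grid()
    labels = np.ones((2, 2, 2), np.int64)
    labels[0, 0, 0] = 2  # component 2 = exactly the first voxel
    atlas = IcaAtlas(grid=grid, mode="hard-labels", labels=labels)
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(8, 5))
    sig = roi_signals(_series(vals, grid), atlas)
    assert np.allclose(sig[1], vals[0])


def test_opposite_series_average_to_zero():
    grid = _grid()
    labels = np.zeros((2, 2, 2), np.int64)
    labels[0, 0, 0] = 1
    labels[0, 0, 1] = 1
    # remaining voxels in a second component so labels partition the mask
    labels[labels == 0] = 2
    atlas = IcaAtlas(grid=grid, mode="hard-labels", labels=labels)
    s = np.sin(np.arange(6.0))
    vals = np.zeros((8, 6))
    vals[0], vals[1] = s, -s
    sig = roi_signals(_series(vals, grid), atlas)
    assert np.allclose(sig[0], 0.0)


def test_roi_signal_matches_bruteforce_mean():
    grid = _grid()
    labels = np.ones((2, 2, 2), np.int64)
    atlas = IcaAtlas(grid=grid, mode="hard-labels", labels=labels)
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(8, 4))
    sig = roi_signals(_series(vals, grid), atlas)
    assert np.allclose(sig[0], vals.mean(axis=0))


def test_soft_weight_mode_matches_weighted_mean():
    grid = _grid()
    rng = np.random.default_rng(2)
    w = rng.random((1, 2, 2, 2))
    atlas = IcaAtlas(grid=grid, mode="soft-weights", weights=w)
    vals = rng.normal(size=(8, 4))
    sig = roi_signals(_series(vals, grid), atlas)
    wm = w[0].ravel() / w[0].sum()
    assert np.allclose(sig[0], wm @ vals)


# -- voxel-to-ROI connectome ------------------------------------------------

def test_voxel_identical_and_negated_roi_signal():
    grid = _grid()
    labels = np.ones((2, 2, 2), np.int64)
    labels[1, 1, 1] = 2
    atlas = IcaAtlas(grid=grid, mode="hard-labels", labels=labels)
    s = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
    vals = np.tile(s, (8, 1))
    vals[-1] = -s  # the single voxel of component 2
    conn = voxel_to_roi_connectome(_series(vals, grid), atlas)
    # channel 0 = ROI 1 signal = s; first voxel identical, last negated
    assert conn[0, 0, 0, 0] == pytest.approx(1.0)
    assert conn[0, 1, 1, 1] == pytest.approx(-1.0)


def test_connectome_matches_scipy_pearson_toy():
    grid = _grid()
    labels = np.ones((2, 2, 2), np.int64)
    labels[0, 0, 0] = 2
    atlas = IcaAtlas(grid=grid, mode="hard-labels", labels=labels)
    vals = np.ones((8, 4))
    vals[0] = [1, 2, 3, 4]       # ROI 2 signal
    vals[1] = [1, 2, 3, 5]       # probe voxel
    vals[2:] = np.random.default_rng(3).normal(size=(6, 4))
    conn = voxel_to_roi_connectome(_series(vals, grid), atlas)
    expected = stats.pearsonr([1, 2, 3, 5], [1, 2, 3, 4])[0]
    assert conn[1].ravel()[1] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_voxel_yields_zero_with_warning():
    grid = _grid()
    atlas = IcaAtlas(grid=grid, mode="hard-labels",
                     labels=np.ones((2, 2, 2), np.int64))
    vals = np.random.default_rng(4).normal(size=(8, 6))
    vals[3] = 2.5  # constant voxel
    with pytest.warns(RuntimeWarning, match="zero-variance"):
        conn = voxel_to_roi_connectome(_series(vals, grid), atlas)
    assert conn[0].ravel()[3] == 0.0


def test_connectome_invariances():
    """Values in [-1, 1] inside the mask, 0 outside; time-reversal invariant."""
    shape = (3, 3, 3)
    mask = np.zeros(shape, bool)
    mask[:2] = True
    grid = MaskedGrid(dims=shape, affine=np.eye(4), mask=mask)
    labels = np.zeros(shape, np.int64)
    labels[mask] = np.resize([1, 2, 3], mask.sum())
    atlas = IcaAtlas(grid=grid, mode="hard-labels", labels=labels)
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(mask.sum(), 20))
    ts = _series(vals, grid)
    conn = voxel_to_roi_connectome(ts, atlas)
    assert np.all(conn[:, mask] <= 1.0) and np.all(conn[:, mask] >= -1.0)
    assert np.all(conn[:, ~mask] == 0.0)
    conn_rev = voxel_to_roi_connectome(_series(vals[:, ::-1], grid), atlas)
    assert np.allclose(conn, conn_rev)


def test_disjoint_noise_segments_give_weakly_related_connectomes():
    grid = _grid()
    atlas = IcaAtlas(grid=grid, mode="hard-labels",
                     labels=np.ones((2, 2, 2), np.int64))
    rng = np.random.default_rng(6)
    ts = _series(rng.normal(size=(8, 2000)), grid)
    seg_a, seg_b = split_timeseries(ts, 1000)
    ca = voxel_to_roi_connectome(seg_a, atlas)[0].ravel()
    cb = voxel_to_roi_connectome(seg_b, atlas)[0].ravel()
    assert abs(stats.pearsonr(ca, cb)[0]) < 0.7  # loose: uncorrelated in expectation


# -- ROI-to-ROI connectome --------------------------------------------------

def test_upper_triangle_counts_and_order():
    m = np.arange(9).reshape(3, 3).astype(float)
    assert np.array_equal(upper_triangle(m), [1.0, 2.0, 5.0])
    assert upper_triangle(np.eye(50)).shape == (1225,)
    assert upper_triangle(np.eye(2)).shape == (1,)


def test_roi_connectome_matches_bruteforce_pairwise_pearson():
    shape = (2, 2, 1)
    grid = MaskedGrid(dims=shape, affine=np.eye(4), mask=np.ones(shape, bool))
    labels = np.arange(1, 5, dtype=np.int64).reshape(shape)
    atlas = IcaAtlas(grid=grid, mode="hard-labels", labels=labels)
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(4, 30))
    R = roi_to_roi_connectome(_series(vals, grid), atlas)
    assert R.shape == (4, 4)
    assert np.allclose(R, R.T) and np.allclose(np.diag(R), 1.0)
    for i in range(4):
        for j in range(i + 1, 4):
            assert R[i, j] == pytest.approx(
                stats.pearsonr(vals[i], vals[j])[0], abs=1e-12)
    assert upper_triangle(R).shape == (6,)
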