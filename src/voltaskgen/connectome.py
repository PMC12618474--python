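"""Voxel-to-ROI and ROI-to-ROI functional connectomes.

The model input is a K-channel volume holding, for each gray-matter voxel,
the Pearson correlation between that voxel's resting-state time series and
the mean time series of each of K ICA-derived ROIs ("full correlation",
i.e. plain Pearson on the supplied, already-cleaned series — no detrending
or filtering happens here).  ROI-to-ROI connectomes (K×K Pearson matrices,
upper triangle vectorized) serve as comparison features downstream.

Zero-variance series yield a correlation of 0 (with a warning) rather than
NaN, so masked border voxels cannot poison training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .volio import MaskedGrid, apply_mask, scatter_mask

__all__ = [
    "BoldTimeSeries",
    "IcaAtlas",
    "split_timeseries",
    "roi_signals",
    "voxel_to_roi_connectome",
    "roi_to_roi_connectome",
    "upper_triangle",
]


@dataclass(frozen=True)
class BoldTimeSeries:
    """Resting-state BOLD series for one subject (or one segment of one).

    ``values`` holds the in-mask voxels in canonical voxel order, shape
    ``(n_mask, T)``.
    """

    subject_id: str
    values: np.ndarray
    grid: MaskedGrid
    segment_id: int = 0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != self.grid.n_mask:
            raise ValueError(
                f"values must be (n_mask, T) = ({self.grid.n_mask}, T), "
                f"got {values.shape}"
            )
        if values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class IcaAtlas:
    """ICA-based parcellation: K spatial components over the grid.

    mode 'hard-labels': ``labels`` is an integer volume (0 = background,
    1..K = component); mode 'soft-weights': ``weights`` is (K, nx, ny, nz)
    of non-negative spatial weights.
    """

    grid: MaskedGrid
    mode: Literal["hard-labels", "soft-weights"]
    labels: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.mode == "hard-labels":
            if self.labels is None:
                raise ValueError("hard-labels mode requires labels")
            labels = np.asarray(self.labels)
            if labels.shape != self.grid.dims:
                raise ValueError("labels shape must equal grid dims")
            labels = labels.astype(np.int64)
            object.__setattr__(self, "labels", labels)
        elif self.mode == "soft-weights":
            if self.weights is None:
                raise ValueError("soft-weights mode requires weights")
            weights = np.asarray(self.weights, dtype=np.float64)
            if weights.ndim != 4 or weights.shape[1:] != self.grid.dims:
                raise ValueError("weights must be (K, nx, ny, nz)")
            object.__setattr__(self, "weights", weights)
        else:
            raise ValueError(f"unknown atlas mode {self.mode!r}")
        for k in range(1, self.n_components + 1):
            if self._support_size(k) == 0:
                raise ValueError(f"component {k} has no in-mask support")

    @property
    def n_components(self) -> int:
        if self.mode == "hard-labels":
            return int(self.labels[self.grid.mask].max())
        return self.weights.shape[0]

    def _support_size(self, k: int) -> int:
        if self.mode == "hard-labels":
            return int(np.sum(self.labels[self.grid.mask] == k))
        return int(np.sum(self.weights[k - 1][self.grid.mask] > 0))

    def masked_labels(self) -> np.ndarray:
        """In-mask labels in canonical voxel order (hard-label mode)."""
        if self.mode != "hard-labels":
            raise ValueError("masked_labels requires hard-label mode")
        return self.labels[self.grid.mask]


def split_timeseries(ts: BoldTimeSeries, segment_length: int) -> list[BoldTimeSeries]:
    """Divide a series into contiguous, non-overlapping segments.

    Segments are order-preserving; a trailing remainder shorter than
    *segment_length* is dropped.  A 4800-timepoint acquisition split at 600
    yields the canonical eight segments.
    """
    if segment_length < 2:
        raise ValueError("segment_length must be >= 2")
    T = ts.n_timepoints
    n_segments = T // segment_length
    if n_segments == 0:
        raise ValueError(
            f"segment_length {segment_length} exceeds series length {T}: "
            "no full segment available"
        )
    return [
        BoldTimeSeries(
            subject_id=ts.subject_id,
            values=ts.values[:, i * segment_length : (i + 1) * segment_length],
            grid=ts.grid,
            segment_id=i,
        )
        for i in range(n_segments)
    ]


def roi_signals(ts: BoldTimeSeries, atlas: IcaAtlas) -> np.ndarray:
    """ROI-averaged time series, shape (K, T).

    Hard-label mode: unweighted mean over the labeled in-mask voxels.
    Soft mode: weight-normalized mean over in-mask voxels.
    """
    atlas.grid.check_compatible(ts.grid)
    K = atlas.n_components
    out = np.empty((K, ts.n_timepoints), dtype=np.float64)
    if atlas.mode == "hard-labels":
        labels = atlas.masked_labels()
        for k in range(1, K + 1):
            sel = labels == k
            if not sel.any():
                raise ValueError(f"component {k} has empty in-mask support")
            out[k - 1] = ts.values[sel].mean(axis=0)
    else:
        w = apply_mask(np.moveaxis(atlas.weights, 0, -1), atlas.grid)  # (n_mask, K)
        totals = w.sum(axis=0)
        if np.any(totals <= 0):
            bad = int(np.flatnonzero(totals <= 0)[0]) + 1
            raise ValueError(f"component {bad} has empty in-mask support")
        out[:] = (w / totals).T @ ts.values
    return out


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of *a* and every row of *b*.

    Zero-variance rows get correlation 0 with a warning.
    """
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.sum(a * a, axis=1))
    sb = np.sqrt(np.sum(b * b, axis=1))
    bad_a, bad_b = sa == 0, sb == 0
    if bad_a.any() or bad_b.any():
        warnings.warn(
            f"zero-variance series ({int(bad_a.sum())} rows / "
            f"{int(bad_b.sum())} cols); their correlations set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    sa = np.where(bad_a, 1.0, sa)
    sb = np.where(bad_b, 1.0, sb)
    r = (a / sa[:, None]) @ (b / sb[:, None]).T
    r[bad_a, :] = 0.0
    r[:, bad_b] = 0.0
    return np.clip(r, -1.0, 1.0)


def voxel_to_roi_connectome(ts: BoldTimeSeries, atlas: IcaAtlas) -> np.ndarray:
    """K-channel voxel-to-ROI connectome, shape (K, nx, ny, nz).

    Channel k at voxel v is Pearson r between voxel v's series and the mean
    signal of ROI k.  Values are exactly 0 outside the mask.
    """
    signals = roi_signals(ts, atlas)  # (K, T)
    r = _pearson_rows(ts.values, signals)  # (n_mask, K)
    vol = scatter_mask(r, ts.grid)  # (nx, ny, nz, K)
    return np.moveaxis(vol, -1, 0)


def roi_to_roi_connectome(ts: BoldTimeSeries, atlas: IcaAtlas) -> np.ndarray:
    """K×K symmetric Pearson matrix of ROI mean signals, unit diagonal."""
    signals = roi_signals(ts, atlas)
    r = _pearson_rows(signals, signals)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Strictly-upper-triangle entries in row-major order, length K(K-1)/2."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]
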