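"""Reconstruction, discriminability, and overlap statistics.

Predicted and actual contrast maps are compared over in-mask voxels:

* reconstruction performance — Pearson r between a subject's predicted and
  actual map;
* similarity matrix — entry (i, j) is r(predicted map of subject i, actual
  map of subject j); its diagonal is the reconstruction performance;
* diagonality index — mean on-diagonal minus mean off-diagonal similarity
  (raw), optionally divided by the mean on-diagonal (normalized).  A
  predictor that emits the same map for everyone (e.g. the group average)
  has identical similarity rows and therefore index exactly 0;
* fingerprinting score — "winner takes all": the fraction of subjects whose
  own actual map is the strict row maximum (ties count as failures);
* Dice overlap of top-percentile activation sets, and its area under the
  curve across a threshold grid (trapezoidal, normalized by the grid span).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "reconstruction_correlation",
    "similarity_matrix",
    "diagonality_index",
    "fingerprinting_score",
    "dice_topk",
    "dice_auc",
    "evaluation_report",
    "DEFAULT_DICE_GRID",
]

#: top-percentile thresholds for the Dice curve: 5% to 50% in steps of 5
DEFAULT_DICE_GRID: tuple[float, ...] = tuple(float(p) for p in range(5, 55, 5))


def _masked_rows(maps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if maps.shape[-mask.ndim:] != mask.shape:
        raise ValueError(f"map shape {maps.shape} does not match mask {mask.shape}")
    single = maps.ndim == mask.ndim
    if single:
        maps = maps[None]
    return maps[:, mask], single


def _row_corr(P: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Pearson r between every row of P and every row of A; zero-variance -> 0."""
    P = P - P.mean(axis=1, keepdims=True)
    A = A - A.mean(axis=1, keepdims=True)
    sp = np.sqrt(np.sum(P * P, axis=1))
    sa = np.sqrt(np.sum(A * A, axis=1))
    bad_p, bad_a = sp == 0, sa == 0
    if bad_p.any() or bad_a.any():
        warnings.warn("zero-variance map; correlation set to 0",
                      RuntimeWarning, stacklevel=3)
    sp = np.where(bad_p, 1.0, sp)
    sa = np.where(bad_a, 1.0, sa)
    r = (P / sp[:, None]) @ (A / sa[:, None]).T
    r[bad_p, :] = 0.0
    r[:, bad_a] = 0.0
    return np.clip(r, -1.0, 1.0)


def reconstruction_correlation(pred, actual, mask) -> np.ndarray | float:
    """Per-subject Pearson r between predicted and actual maps over the mask."""
    P, single_p = _masked_rows(pred, mask)
    A, single_a = _masked_rows(actual, mask)
    if P.shape[0] != A.shape[0]:
        raise ValueError("prediction and actual subject counts differ")
    r = np.array([_row_corr(P[i : i + 1], A[i : i + 1])[0, 0]
                  for i in range(P.shape[0])])
    return float(r[0]) if (single_p and single_a) else r


def similarity_matrix(preds, actuals, mask) -> np.ndarray:
    """N x N matrix with entry (i, j) = r(pred_i, actual_j) over the mask."""
    P, _ = _masked_rows(preds, mask)
    A, _ = _masked_rows(actuals, mask)
    if P.shape[0] != A.shape[0]:
        raise ValueError("subject lists must be equal and aligned")
    return _row_corr(P, A)


def diagonality_index(S: np.ndarray, normalized: bool = True) -> float:
    """mean(diag) - mean(off-diag); normalized form divides by mean(diag)."""
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diag = np.diagonal(S)
    mean_diag = diag.mean()
    mean_off = (S.sum() - diag.sum()) / (n * n - n)
    raw = mean_diag - mean_off
    if not normalized:
        return float(raw)
    if mean_diag == 0:
        raise ZeroDivisionError("mean on-diagonal similarity is 0; "
                                "normalized index undefined")
    return float(raw / mean_diag)


def fingerprinting_score(S: np.ndarray) -> float:
    """Fraction of rows whose diagonal entry is the strict row maximum."""
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ValueError("similarity matrix must be square with N >= 2")
    n = S.shape[0]
    hits = 0
    for i in range(n):
        row = S[i]
        if row[i] > np.max(np.delete(row, i)):
            hits += 1
    return hits / n


def _top_set(values: np.ndarray, top_pct: float) -> np.ndarray:
    """Indices of the top-pct values; ties at the cut broken by voxel order."""
    n = values.shape[0]
    k = int(round(top_pct / 100.0 * n))
    if k < 1:
        raise ValueError(
            f"top {top_pct}% of {n} voxels is an empty set")
    order = np.argsort(-values, kind="stable")
    return order[:k]


def dice_topk(pred, actual, mask, top_pct: float) -> float:
    """Dice overlap of the top-percentile voxel sets of two maps."""
    if not 0 < top_pct < 100:
        raise ValueError("top_pct must be in (0, 100)")
    P, _ = _masked_rows(pred, mask)
    A, _ = _masked_rows(actual, mask)
    sp = _top_set(P[0], top_pct)
    sa = _top_set(A[0], top_pct)
    inter = len(np.intersect1d(sp, sa, assume_unique=True))
    return 2.0 * inter / (len(sp) + len(sa))


def dice_auc(pred, actual, mask,
             grid_of_pcts: Sequence[float] = DEFAULT_DICE_GRID) -> float:
    """Trapezoidal integral of Dice over the threshold grid / grid span."""
    pcts = np.asarray(sorted(grid_of_pcts), dtype=float)
    if pcts.size < 2:
        raise ValueError("need at least two thresholds for an AUC")
    dice = np.array([dice_topk(pred, actual, mask, p) for p in pcts])
    return float(np.trapezoid(dice, pcts) / (pcts[-1] - pcts[0]))


def evaluation_report(preds, actuals, mask, method: str, contrast: str,
                      subject_ids: Sequence[str] | None = None,
                      dice_grid: Sequence[float] = DEFAULT_DICE_GRID) -> pd.DataFrame:
    """Tidy per-subject and cohort-level metrics for one method and contrast.

    Returns a long-format frame (method, contrast, subject, metric, value);
    cohort-level rows (diagonality, fingerprinting) use subject = ''.
    The Dice threshold grid used is recorded as a 'dice_grid' row.
    """
    preds = np.asarray(preds, dtype=np.float64)
    n = preds.shape[0]
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(n)]
    rows = []
    r = reconstruction_correlation(preds, actuals, mask)
    for sid, ri in zip(subject_ids, np.atleast_1d(r)):
        rows.append((method, contrast, sid, "reconstruction_r", float(ri)))
    for sid, p, a in zip(subject_ids, preds, np.asarray(actuals, dtype=np.float64)):
        rows.append((method, contrast, sid, "dice_auc",
                     dice_auc(p, a, mask, dice_grid)))
    S = similarity_matrix(preds, actuals, mask)
    rows.append((method, contrast, "", "diagonality_raw",
                 diagonality_index(S, normalized=False)))
    rows.append((method, contrast, "", "diagonality_normalized",
                 diagonality_index(S, normalized=True)))
    rows.append((method, contrast, "", "fingerprinting", fingerprinting_score(S)))
    df = pd.DataFrame(rows, columns=["method", "contrast", "subject",
                                     "metric", "value"])
    df.attrs["dice_grid"] = tuple(float(p) for p in dice_grid)
    return df
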