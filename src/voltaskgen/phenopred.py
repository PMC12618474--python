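"""Downstream phenotype-prediction validation harness.

Feature matrices are built either from contrast maps (one column per
gray-matter voxel, canonical order) or from ROI-to-ROI connectomes (the
K(K-1)/2 strictly-upper-triangle correlations).  Targets are predicted with
L2-regularized linear models inside 5-fold cross-validation; the ridge
penalty is tied to dimensionality, ``alpha = n_features / n_train`` of each
training fold, so heavily parameterized map features are regularized more
than compact connectome features.  Continuous targets are scored by Pearson
r between held-out predictions and truth, binary targets by balanced
accuracy.  Significance comes from a permutation test (targets shuffled,
the full CV rerun per permutation) with the plus-one p estimator
``p = (1 + #{null >= observed}) / (P + 1)``, which is never 0.  Modalities
are compared by a paired t-test over fold scores with a sign-flip
permutation null, Benjamini-Hochberg FDR across comparisons, and Cliff's
delta as the effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge, RidgeClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .connectome import upper_triangle
from .volio import MaskedGrid, apply_mask

__all__ = [
    "CvPredictionResult",
    "ModalityComparison",
    "build_features",
    "ridge_alpha",
    "ridge_cv_predict",
    "permutation_pvalue",
    "compare_modalities",
    "cliffs_delta",
    "fdr_adjust",
]


@dataclass(frozen=True)
class CvPredictionResult:
    """Cross-validated prediction scores for one modality and variable."""

    modality: str
    variable: str
    fold_scores: tuple[float, ...]
    mean_score: float
    metric: str
    n: int
    permutation_p: float | None = None


@dataclass(frozen=True)
class ModalityComparison:
    """Paired comparison of two modalities' fold scores."""

    modality_a: str
    modality_b: str
    t_statistic: float
    permutation_p: float
    cliffs_delta: float
    fdr_p: float | None = None


def build_features(maps=None, connectomes=None,
                   grid: MaskedGrid | None = None) -> np.ndarray:
    """Subjects-by-features matrix from maps or ROI-to-ROI connectomes.

    Exactly one of *maps* (S, nx, ny, nz; requires *grid*) or *connectomes*
    (S, K, K) must be given.
    """
    if (maps is None) == (connectomes is None):
        raise ValueError("give exactly one of maps or connectomes")
    if maps is not None:
        if grid is None:
            raise ValueError("map features require the grid")
        maps = np.asarray(maps, dtype=np.float64)
        return np.stack([apply_mask(m, grid) for m in maps])
    connectomes = np.asarray(connectomes, dtype=np.float64)
    return np.stack([upper_triangle(c) for c in connectomes])


def ridge_alpha(n_features: int, n_train: int) -> float:
    """Dimension-tied regularization strength: n_features / n_train."""
    return n_features / n_train


def _folds(y: np.ndarray, task_type: str, n_folds: int, seed: int):
    if task_type == "binary":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
        return splitter.split(np.zeros_like(y), y)
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return splitter.split(np.zeros_like(y))


def ridge_cv_predict(features: np.ndarray, target: np.ndarray,
                     task_type: str = "continuous", n_folds: int = 5,
                     seed: int = 0, modality: str = "features",
                     variable: str = "target") -> CvPredictionResult:
    """Cross-validated ridge prediction with dimension-tied regularization.

    ``alpha = n_features / n_train`` per training fold.  Continuous targets
    use :class:`~sklearn.linear_model.Ridge` scored by Pearson r;
    binary {0,1} targets use a ridge classifier scored by balanced accuracy
    (folds stratified by class).
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and target must align")
    if np.isnan(y).any():
        raise ValueError("missing targets must be filtered before prediction")
    if X.shape[0] < n_folds:
        raise ValueError("need at least n_folds subjects")
    if task_type not in ("continuous", "binary"):
        raise ValueError(f"unknown task_type {task_type!r}")
    if task_type == "binary" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary targets must be coded {0, 1}")

    scores = []
    for train_idx, test_idx in _folds(y, task_type, n_folds, seed):
        alpha = ridge_alpha(X.shape[1], len(train_idx))
        if task_type == "binary":
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError("single-class training fold")
            est = RidgeClassifier(alpha=alpha)
            est.fit(X[train_idx], y[train_idx])
            scores.append(balanced_accuracy_score(y[test_idx],
                                                  est.predict(X[test_idx])))
        else:
            est = Ridge(alpha=alpha)
            est.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
            if np.std(pred) == 0 or np.std(y[test_idx]) == 0:
                scores.append(0.0)
            else:
                scores.append(float(stats.pearsonr(pred, y[test_idx])[0]))
    scores = tuple(float(s) for s in scores)
    return CvPredictionResult(
        modality=modality, variable=variable, fold_scores=scores,
        mean_score=float(np.mean(scores)),
        metric="balanced_accuracy" if task_type == "binary" else "pearson_r",
        n=X.shape[0])


def permutation_pvalue(features: np.ndarray, target: np.ndarray,
                       observed_mean: float, task_type: str = "continuous",
                       n_permutations: int = 1000, n_folds: int = 5,
                       seed: int = 0) -> float:
    """Plus-one permutation p for a CV mean score.

    Targets are permuted *n_permutations* times and the full CV rerun per
    permutation; ``p = (1 + #{null mean >= observed}) / (P + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    y = np.asarray(target, dtype=np.float64)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        null = ridge_cv_predict(features, perm, task_type=task_type,
                                n_folds=n_folds, seed=seed)
        if null.mean_score >= observed_mean:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


def cliffs_delta(a, b) -> float:
    """(#{a > b} - #{a < b}) / (n_a * n_b) over all cross pairs."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    diff = a[:, None] - b[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / diff.size)


def compare_modalities(scores_a, scores_b, n_permutations: int = 1000,
                       seed: int = 0, modality_a: str = "a",
                       modality_b: str = "b") -> ModalityComparison:
    """Paired t over fold scores with a sign-flip permutation null.

    The null distribution flips the sign of each paired difference at
    random; the two-sided p is the plus-one proportion of permuted |t| at
    least as extreme as the observed |t|.  Zero-variance differences are
    reported as a no-difference result (t = 0, p = 1).  Run only between
    modalities that individually survived permutation testing.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fold score vectors must align")
    if a.size < 2:
        raise ValueError("need at least 2 folds")
    d = a - b
    delta = cliffs_delta(a, b)
    sd = d.std(ddof=1)
    if sd == 0:
        return ModalityComparison(modality_a, modality_b, 0.0, 1.0, delta)
    t_obs = float(d.mean() / (sd / np.sqrt(d.size)))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=d.size)
        dp = d * signs
        sdp = dp.std(ddof=1)
        t_perm = 0.0 if sdp == 0 else dp.mean() / (sdp / np.sqrt(d.size))
        if abs(t_perm) >= abs(t_obs):
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return ModalityComparison(modality_a, modality_b, t_obs, p, delta)


def fdr_adjust(comparisons: list[ModalityComparison]) -> list[ModalityComparison]:
    """Benjamini-Hochberg FDR across a family of modality comparisons."""
    if not comparisons:
        return []
    pvals = [c.permutation_p for c in comparisons]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [ModalityComparison(c.modality_a, c.modality_b, c.t_statistic,
                               c.permutation_p, c.cliffs_delta, float(q))
            for c, q in zip(comparisons, adj)]
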