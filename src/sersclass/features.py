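"""Univariate feature scoring (t, w, RELIEF), PCA, and score-then-PCA chains.

Scorers measure, per wavenumber, how well that single feature separates the
two classes:

* ``t`` — two-sample t-statistic ``|mu0 - mu1| / sqrt(s1^2/n1 + s0^2/n0)``;
* ``w`` — signal-to-noise (Golub-style) ratio ``|mu0 - mu1| / (s1 + s0)``;
* ``relief`` — per-feature RELIEF weight: mean over samples of
  ``|x - miss(x)| - |x - hit(x)|``, where hit/miss are the nearest same- /
  opposite-class sample values in that feature alone.

Standard deviations are sample (n-1) throughout.  A zero denominator with
equal class means scores 0; a zero denominator with unequal means (perfectly
separated, zero-variance feature) is flagged and scored above every finite
score.  PCA standardizes each feature (constant features get unit scale) and
eigen-decomposes the covariance matrix; the largest-magnitude loading of
each component is made positive so signs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import CLASSES


@dataclass
class FeatureRanking:
    """Per-feature scores with a descending-score ranking.

    ``order`` sorts features by descending score, ties broken by ascending
    feature index (i.e. ascending wavenumber when columns are in grid
    order).  ``flagged`` marks zero-denominator/unequal-mean features whose
    score was set just above the largest finite score.
    """

    scores: np.ndarray
    order: np.ndarray
    k: int
    method: str
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def selected(self) -> np.ndarray:
        """Indices of the top-k features."""
        return self.order[: self.k]


def _class_split(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=object)
    groups = []
    for cls in CLASSES:
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} absent from labels")
        groups.append(idx)
    return groups[0], groups[1]


def _rank(scores: np.ndarray, k: int, method: str, flagged: np.ndarray) -> FeatureRanking:
    # stable sort on (-score, index): descending score, ascending index on ties
    order = np.lexsort((np.arange(scores.size), -scores))
    return FeatureRanking(scores=scores, order=order, k=int(k), method=method, flagged=flagged)


def _mean_diff_ratio(
    X: np.ndarray, labels: np.ndarray, denom_fn, k: int, method: str
) -> FeatureRanking:
    i0, i1 = _class_split(X, labels)
    if min(i0.size, i1.size) < 2:
        raise ValueError("each class needs at least 2 samples")
    X0, X1 = X[i0], X[i1]
    num = np.abs(X0.mean(axis=0) - X1.mean(axis=0))
    denom = denom_fn(X0.std(axis=0, ddof=1), X1.std(axis=0, ddof=1), i0.size, i1.size)
    scores = np.zeros(X.shape[1])
    ok = denom > 0
    scores[ok] = num[ok] / denom[ok]
    flagged = (~ok) & (num > 0)
    if flagged.any():
        finite_max = scores[ok].max() if ok.any() else 0.0
        scores[flagged] = finite_max + 1.0
    return _rank(scores, k, method, flagged)


def score_t(X: np.ndarray, labels: np.ndarray, k: int | None = None) -> FeatureRanking:
    """Two-sample t-statistic per feature (unequal-variance form)."""
    X = np.asarray(X, dtype=float)
    k = X.shape[1] if k is None else k
    return _mean_diff_ratio(
        X, labels, lambda s0, s1, n0, n1: np.sqrt(s1**2 / n1 + s0**2 / n0), k, "t"
    )


def score_w(X: np.ndarray, labels: np.ndarray, k: int | None = None) -> FeatureRanking:
    """Signal-to-noise class-separation score |mu0-mu1| / (s0 + s1)."""
    X = np.asarray(X, dtype=float)
    k = X.shape[1] if k is None else k
    return _mean_diff_ratio(X, labels, lambda s0, s1, n0, n1: s0 + s1, k, "w")


def score_relief(X: np.ndarray, labels: np.ndarray, k: int | None = None) -> FeatureRanking:
    """Per-feature RELIEF weight.

    For each sample and each feature independently, the hit (miss) is the
    value of the nearest other same-class (opposite-class) sample in that
    feature alone; distance ties resolve to the lowest sample index (the
    choice cannot change the weight, which depends on the distance only).
    The feature weight is the mean of ``|x - miss| - |x - hit|`` over
    samples.
    """
    X = np.asarray(X, dtype=float)
    k = X.shape[1] if k is None else k
    i0, i1 = _class_split(X, labels)
    if min(i0.size, i1.size) < 2:
        raise ValueError("each class needs at least 2 samples (no hit otherwise)")
    n, p = X.shape
    labels = np.asarray(labels, dtype=object)
    same_mask = labels[:, None] == labels[None, :]
    np.fill_diagonal(same_mask, False)  # a sample is not its own hit
    opp_mask = labels[:, None] != labels[None, :]
    scores = np.empty(p)
    for j in range(p):
        diff = np.abs(X[:, j, None] - X[None, :, j])
        hit_d = np.where(same_mask, diff, np.inf).min(axis=1)
        miss_d = np.where(opp_mask, diff, np.inf).min(axis=1)
        scores[j] = np.mean(miss_d - hit_d)
    return _rank(scores, k, "relief", np.zeros(p, dtype=bool))


@dataclass
class PCAModel:
    """Standardizing PCA fitted on the covariance of z-scored data."""

    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # rows = eigenvectors, descending eigenvalue
    eigenvalues: np.ndarray


def fit_pca(X: np.ndarray) -> PCAModel:
    """Fit PCA on standardized data (constant features get unit scale)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale
    # Eigenvectors of the covariance via thin SVD of Z: for n << p this is
    # far cheaper than forming the p x p covariance, and identical on the
    # nonzero spectrum (covariance eigenvalues are S^2 / (n-1)).
    _, svals, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = svals**2 / (X.shape[0] - 1)
    components = vt
    # sign convention: make each component's largest-|loading| positive
    for row in components:
        pivot = np.argmax(np.abs(row))
        if row[pivot] < 0:
            row *= -1
    return PCAModel(center=center, scale=scale, components=components, eigenvalues=eigvals)


def transform_pca(model: PCAModel, X: np.ndarray, k: int) -> np.ndarray:
    """Project (standardized) data onto the top-k principal components."""
    X = np.asarray(X, dtype=float)
    if k > model.components.shape[0]:
        raise ValueError(f"k={k} exceeds available components")
    Z = (X - model.center) / model.scale
    return Z @ model.components[:k].T


def inverse_transform_pca(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Map component scores back to standardized feature space."""
    k = scores.shape[1]
    return scores @ model.components[:k]


_SCORERS = {"t": score_t, "w": score_w, "relief": score_relief}


def chain_select_pca(
    X: np.ndarray,
    labels: np.ndarray,
    method: str,
    k_select: int,
    k_pca: int,
) -> tuple[np.ndarray, dict]:
    """Select top-``k_select`` features by ``method`` then reduce to
    ``k_pca`` principal components; returns the reduced matrix and a
    provenance dict recording the selected feature indices."""
    if k_pca > k_select:
        raise ValueError("k_pca must not exceed k_select")
    ranking = _SCORERS[method](X, labels, k=k_select)
    sel = np.sort(ranking.selected)
    model = fit_pca(np.asarray(X, dtype=float)[:, sel])
    reduced = transform_pca(model, np.asarray(X, dtype=float)[:, sel], k_pca)
    provenance = {
        "method": method,
        "k_select": k_select,
        "k_pca": k_pca,
        "selected_indices": sel,
        "ranking": ranking,
        "pca_model": model,
    }
    return reduced, provenance
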