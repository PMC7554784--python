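"""Class-constrained k-fold cross-validation with kNN/SVM classifiers.

The fold plan guarantees every test fold holds at least one spectrum of
each class, so the minority class caps the fold count: with 37 control and
14 TRC spectra the default is a 14-fold CV with exactly one TRC per fold
and two or three controls.  Fold accuracies aggregate with the population
(divide-by-fold-count) standard deviation.

Two protocols are provided for feature reduction inside CV:

* ``safe`` (default) — selection/PCA is fitted on the training folds only
  and applied to the held-out fold (no information leakage);
* ``paper`` — selection/PCA is fitted once on the full dataset before
  splitting.  Small-sample spectroscopy studies commonly report this
  protocol; it is kept as an explicit, recorded mode.

The grid runner evaluates every combination of data type, normalization,
reduction method, dimension count and classifier, and returns rows in the
summary-table schema sorted by CV accuracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.svm import SVC

from .dataset import CLASSES, SpectrumSet
from .features import (
    FeatureRanking,
    PCAModel,
    _SCORERS,
    fit_pca,
    transform_pca,
)
from .peaks import build_peak_matrix
from .preprocess import BaselineConfig, correct_baseline, normalize_max

SVM_KERNELS = ("linear", "poly", "sigmoid", "rbf")


@dataclass
class FoldPlan:
    """Assignment of each spectrum to one test fold."""

    fold_count: int
    assignment: np.ndarray  # fold index per spectrum

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_folds(labels, fold_count: int | None = None, seed: int = 0) -> FoldPlan:
    """Build a class-constrained fold plan.

    Minority-class spectra are shuffled and dealt one per fold; the
    majority class is shuffled and dealt round-robin.  The default fold
    count is the minority-class size, the largest count for which every
    fold can contain one of each class.
    """
    labels = np.asarray(labels, dtype=object)
    counts = {cls: int(np.sum(labels == cls)) for cls in CLASSES}
    for cls, cnt in counts.items():
        if cnt == 0:
            raise ValueError(f"class {cls!r} absent")
    minority = min(CLASSES, key=lambda c: counts[c])
    if fold_count is None:
        fold_count = counts[minority]
    if fold_count > counts[minority]:
        raise ValueError(
            f"fold_count {fold_count} exceeds minority-class size {counts[minority]}"
        )
    if fold_count < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    for cls in CLASSES:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % fold_count
    return FoldPlan(fold_count=fold_count, assignment=assignment)


def knn_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    k: int,
) -> np.ndarray:
    """k-nearest-neighbour majority vote (Euclidean metric).

    Neighbour order breaks distance ties by lower training index; a tied
    vote (possible for even k) goes to the nearest neighbour's class.
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=float))
    train_y = np.asarray(train_y, dtype=object)
    n = train_X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if k > n:
        raise ValueError(f"k={k} exceeds training size {n}")
    preds = np.empty(test_X.shape[0], dtype=object)
    for q in range(test_X.shape[0]):
        d = np.linalg.norm(train_X - test_X[q], axis=1)
        order = np.lexsort((np.arange(n), d))[:k]
        votes = train_y[order]
        best, best_count = None, -1
        for cls in CLASSES:
            cnt = int(np.sum(votes == cls))
            if cnt > best_count:
                best, best_count = cls, cnt
        # tie in the vote -> class of the single nearest neighbour
        tied = [cls for cls in CLASSES if int(np.sum(votes == cls)) == best_count]
        preds[q] = votes[0] if len(tied) > 1 else best
    return preds


def svm_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    degree: int = 3,
    gamma: str | float = "scale",
    coef0: float = 0.0,
) -> np.ndarray:
    """Soft-margin SVM prediction (delegates to a standard solver)."""
    if kernel not in SVM_KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {SVM_KERNELS}")
    train_y = np.asarray(train_y, dtype=object)
    if len(set(train_y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(kernel=kernel, C=C, degree=degree, gamma=gamma, coef0=coef0)
    clf.fit(np.asarray(train_X, dtype=float), train_y.astype(str))
    return clf.predict(np.asarray(test_X, dtype=float)).astype(object)


@dataclass
class Reduction:
    """Feature-reduction step of the CV pipeline.

    ``method`` is one of ``none | t | w | relief | pca``; ``dims`` is the
    number of selected features (or components for plain PCA); ``pca_dims``
    chains a PCA of that many components after score-based selection.
    """

    method: str = "none"
    dims: int | None = None
    pca_dims: int | None = None

    def display_name(self) -> str:
        names = {"t": "t-score", "w": "MIT", "relief": "RELIEF"}
        if self.method == "none":
            return "none"
        if self.method == "pca":
            return f"PCA = {self.dims}"
        base = names[self.method]
        if self.pca_dims is not None:
            return f"{base} + PCA = {self.pca_dims}"
        return base

    def fit(self, X: np.ndarray, labels) -> "FittedReduction":
        X = np.asarray(X, dtype=float)
        if self.method == "none":
            return FittedReduction(self)
        if self.method == "pca":
            return FittedReduction(self, pca_model=fit_pca(X))
        ranking = _SCORERS[self.method](X, labels, k=self.dims)
        sel = np.sort(ranking.selected)
        model = None
        if self.pca_dims is not None:
            if self.pca_dims > self.dims:
                raise ValueError("pca_dims must not exceed dims")
            model = fit_pca(X[:, sel])
        return FittedReduction(self, selected=sel, ranking=ranking, pca_model=model)


@dataclass
class FittedReduction:
    spec: Reduction
    selected: np.ndarray | None = None
    ranking: FeatureRanking | None = None
    pca_model: PCAModel | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.spec.method == "none":
            return X
        if self.spec.method == "pca":
            return transform_pca(self.pca_model, X, self.spec.dims)
        Xs = X[:, self.selected]
        if self.pca_model is not None:
            return transform_pca(self.pca_model, Xs, self.spec.pca_dims)
        return Xs


@dataclass
class Classifier:
    """Classifier leg of the pipeline: kNN (with ``k``) or SVM (with kernel)."""

    name: str = "knn"
    k: int = 1
    kernel: str = "linear"
    C: float = 1.0
    degree: int = 3

    def display_name(self) -> str:
        if self.name == "knn":
            return f"kNN k = {self.k}"
        return f"SVM {self.kernel}"

    def predict(self, train_X, train_y, test_X) -> np.ndarray:
        if self.name == "knn":
            return knn_classify(train_X, train_y, test_X, k=self.k)
        if self.name == "svm":
            return svm_classify(
                train_X, train_y, test_X, kernel=self.kernel, C=self.C, degree=self.degree
            )
        raise ValueError(f"unknown classifier {self.name!r}")


def _population_std(values: np.ndarray) -> float:
    return float(np.std(np.asarray(values, dtype=float), ddof=0))


@dataclass
class CVResult:
    """Aggregated cross-validation outcome for one pipeline configuration."""

    fold_accuracies: np.ndarray
    train_accuracies: np.ndarray
    cv_acc: float
    cv_std: float
    train_cv: float
    train_std: float
    overfit: bool
    classifier: str = ""
    reduction_method: str = ""
    dimensions: int = 0
    data_type: str = ""
    normalized: bool = False
    mode: str = "safe"
    seed: int = 0

    @classmethod
    def from_fold_accuracies(
        cls, fold_accuracies, train_accuracies=None, **config
    ) -> "CVResult":
        """Aggregate per-fold test (and optional training) accuracies.

        Means are plain averages; standard deviations use the population
        (divide-by-fold-count) formula.
        """
        fa = np.asarray(fold_accuracies, dtype=float)
        if fa.size == 0:
            raise ValueError("no fold accuracies")
        if np.any((fa < 0) | (fa > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        ta = np.asarray(
            train_accuracies if train_accuracies is not None else [], dtype=float
        )
        cv_acc = float(fa.mean())
        cv_std = _population_std(fa)
        train_cv = float(ta.mean()) if ta.size else float("nan")
        train_std = _population_std(ta) if ta.size else float("nan")
        overfit = bool(ta.size) and train_cv > cv_acc
        return cls(
            fold_accuracies=fa,
            train_accuracies=ta,
            cv_acc=cv_acc,
            cv_std=cv_std,
            train_cv=train_cv,
            train_std=train_std,
            overfit=overfit,
            **config,
        )


def cross_validate(
    X: np.ndarray,
    labels,
    plan: FoldPlan,
    classifier: Classifier,
    reduction: Reduction | None = None,
    paper_mode: bool = False,
    **config,
) -> CVResult:
    """Run the constrained k-fold CV for one pipeline configuration.

    In the default (``safe``) mode the reduction is fitted on the training
    folds only; ``paper_mode`` fits it once on the full dataset first.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    reduction = reduction or Reduction()
    if paper_mode:
        fitted_full = reduction.fit(X, labels)
        X_full = fitted_full.transform(X)
    fold_accs, train_accs = [], []
    for f in range(plan.fold_count):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        if len(set(labels[tr])) < 2:
            raise ValueError(f"training portion of fold {f} has a single class")
        if paper_mode:
            Xtr, Xte = X_full[tr], X_full[te]
        else:
            fitted = reduction.fit(X[tr], labels[tr])
            Xtr, Xte = fitted.transform(X[tr]), fitted.transform(X[te])
        pred_te = classifier.predict(Xtr, labels[tr], Xte)
        pred_tr = classifier.predict(Xtr, labels[tr], Xtr)
        fold_accs.append(float(np.mean(pred_te == labels[te])))
        train_accs.append(float(np.mean(pred_tr == labels[tr])))
    dims = reduction.dims if reduction.method != "none" else X.shape[1]
    return CVResult.from_fold_accuracies(
        fold_accs,
        train_accs,
        classifier=classifier.display_name(),
        reduction_method=reduction.display_name(),
        dimensions=int(dims),
        mode="paper" if paper_mode else "safe",
        **config,
    )


@dataclass
class GridSpec:
    """Combinatorial grid: every combination is cross-validated.

    ``data_types`` draw from ``raw`` (as measured), ``corrected``
    (baseline-removed) and ``peaks`` (peak matrix built from the corrected
    spectra); normalization divides each spectrum by its maximum before
    feature extraction.
    """

    data_types: tuple = ("raw", "corrected", "peaks")
    normalizations: tuple = (False, True)
    reductions: tuple = (
        Reduction("t", 35),
        Reduction("w", 35),
        Reduction("relief", 35),
        Reduction("pca", 3),
        Reduction("t", 35, pca_dims=3),
        Reduction("w", 35, pca_dims=3),
        Reduction("relief", 35, pca_dims=3),
    )
    classifiers: tuple = (
        Classifier("knn", k=1),
        Classifier("knn", k=3),
        Classifier("svm", kernel="linear"),
        Classifier("svm", kernel="rbf"),
        Classifier("svm", kernel="sigmoid"),
        Classifier("svm", kernel="poly"),
    )
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    min_prominence: float = 0.0


def _data_variants(sset: SpectrumSet, spec: GridSpec) -> dict:
    corrected = correct_baseline(sset, spec.baseline)
    variants = {}
    for norm in spec.normalizations:
        raw_s = normalize_max(sset) if norm else sset
        cor_s = normalize_max(corrected) if norm else corrected
        variants[("raw", norm)] = (raw_s.intensities, sset.grid)
        variants[("corrected", norm)] = (cor_s.intensities, sset.grid)
        pm = build_peak_matrix(cor_s, spec.min_prominence)
        variants[("peaks", norm)] = (pm.values, pm.peak_grid)
    return variants


def run_grid(
    sset: SpectrumSet,
    spec: GridSpec | None = None,
    seed: int = 0,
    paper_mode: bool = False,
    fold_count: int | None = None,
) -> list[CVResult]:
    """Cross-validate every grid combination; rows sorted by cv_acc descending."""
    spec = spec or GridSpec()
    if not (spec.data_types and spec.reductions and spec.classifiers):
        raise ValueError("empty grid")
    plan = make_folds(sset.labels, fold_count=fold_count, seed=seed)
    variants = _data_variants(sset, spec)
    results = []
    for data_type, norm, red, clf in itertools.product(
        spec.data_types, spec.normalizations, spec.reductions, spec.classifiers
    ):
        X, feat_grid = variants[(data_type, norm)]
        if red.method != "none" and red.dims is not None and red.dims > X.shape[1]:
            red = replace(red, dims=X.shape[1])
        res = cross_validate(
            X,
            sset.labels,
            plan,
            clf,
            red,
            paper_mode=paper_mode,
            data_type=data_type,
            normalized=bool(norm),
            seed=seed,
        )
        results.append(res)
    results.sort(key=lambda r: -r.cv_acc)
    return results
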