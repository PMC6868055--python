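"""PCA-based feature-importance ranking and the SVM validation protocol.

Feature importance is computed from a principal component analysis of the
z-scored feature matrix: with unit-norm loading vectors ``coeff[:, j]``
and explained-variance percentages ``explained[j]``, the importance of
feature i is

    importance_i = sum_j coeff[i, j]**2 * explained[j].

With all components retained the loadings form an orthonormal basis, so
the importances sum exactly to the total explained-variance percentage
(100). Importance is invariant to loading sign flips because the loadings
enter squared.

A caution on normalization: if every column is z-scored to unit variance
and all components are retained, this importance collapses to a constant —
sum_j coeff_ij^2 * lambda_j is the i-th diagonal element of the
correlation matrix, which is 1 for every feature — and the ranking is
meaningless. The metric discriminates only while variance differences
survive normalization. The default here is therefore min-max range
scaling to [0, 1]: it removes units (so pixel distances and 16-bit
intensities are comparable) while a feature whose distribution is split
by a class effect keeps an elevated variance and ranks high. Z-scoring
and no scaling remain available via ``scale=``.

Importance claims are validated by comparing held-out accuracies of
Gaussian-kernel SVMs trained on different feature subsets over repeated
70/30 stratified splits, with a two-sided Wilcoxon rank-sum test between
the accuracy distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ranksums
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["ImportanceRanking", "AccuracyDistribution", "zscore",
           "range_scale", "pca_importance", "train_gaussian_svm",
           "repeated_accuracy", "compare_distributions"]


@dataclass
class ImportanceRanking:
    """Per-feature PCA importance scores with the quantities they came from."""

    feature_names: list
    scores: np.ndarray          # importance per feature, same order
    ranks: np.ndarray           # 1 = most important
    loadings: np.ndarray        # (n_features, n_components), unit-norm columns
    explained: np.ndarray       # explained-variance percentages per component

    def top(self, k: int) -> list:
        order = np.argsort(self.ranks)
        return [self.feature_names[i] for i in order[:k]]

    def bottom(self, k: int) -> list:
        order = np.argsort(self.ranks)
        return [self.feature_names[i] for i in order[-k:]]


@dataclass
class AccuracyDistribution:
    """Held-out accuracies over repeated random splits of one feature subset."""

    accuracies: np.ndarray
    feature_subset: list
    split_seeds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))


def zscore(matrix: np.ndarray, feature_names: list | None = None) -> np.ndarray:
    """Column-wise z-score (mean 0, sample std 1, ddof=1).

    Raises on constant columns, naming the offending feature: a feature
    with zero variance cannot be normalized and should have been flagged
    upstream.
    """
    x = np.asarray(matrix, dtype=float)
    std = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(std == 0)
    if bad.size:
        names = ([feature_names[i] for i in bad] if feature_names
                 else bad.tolist())
        raise ValueError(f"constant feature column(s): {names}")
    return (x - x.mean(axis=0)) / std


def range_scale(matrix: np.ndarray) -> np.ndarray:
    """Min-max scale each column to [0, 1]; constant columns map to 0."""
    x = np.asarray(matrix, dtype=float)
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span[span == 0] = 1.0
    return (x - lo) / span


def pca_importance(matrix: np.ndarray,
                   feature_names: list | None = None,
                   scale: str | None = "range") -> ImportanceRanking:
    """Rank features by squared PCA loadings weighted by explained variance.

    ``scale`` is ``"range"`` (default; min-max to [0, 1]), ``"zscore"``
    (degenerate for this metric when all components are retained — see the
    module docstring) or ``None`` (raw covariance PCA). All components
    with nonzero variance are retained; near-zero-variance components are
    dropped with a warning when the input is rank-deficient.
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    if scale == "range":
        x = range_scale(x)
    elif scale == "zscore":
        x = zscore(x, feature_names)
    elif scale is not None:
        raise ValueError(f"unknown scale {scale!r}")
    pca = PCA(n_components=None)
    pca.fit(x)
    keep = pca.explained_variance_ > 1e-12 * max(pca.explained_variance_[0], 1.0)
    if not np.all(keep):
        import warnings
        warnings.warn(f"rank-deficient feature matrix: dropping "
                      f"{int((~keep).sum())} near-zero-variance component(s)")
    loadings = pca.components_[keep].T            # (p, k), unit-norm columns
    explained = pca.explained_variance_ratio_[keep] * 100.0
    scores = (loadings**2 * explained[None, :]).sum(axis=1)
    order = np.argsort(-scores)
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return ImportanceRanking(list(feature_names), scores, ranks,
                             loadings, explained)


def _subset_columns(matrix: np.ndarray, feature_names: list,
                    subset: list) -> np.ndarray:
    idx = [feature_names.index(f) for f in subset]
    return np.asarray(matrix, dtype=float)[:, idx]


def train_gaussian_svm(matrix: np.ndarray, labels: np.ndarray,
                       feature_subset: list | None = None,
                       feature_names: list | None = None,
                       test_fraction: float = 0.3, seed: int = 0,
                       C: float = 1.0, gamma: str | float = "scale",
                       max_resplits: int = 5) -> float:
    """One 70/30 stratified split, Gaussian-kernel SVM fit, held-out accuracy.

    Columns are standardized on the training fold only. A degenerate
    single-class training fold triggers a re-split with the next seed.
    """
    x = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if feature_subset is not None:
        if feature_names is None:
            raise ValueError("feature_subset requires feature_names")
        x = _subset_columns(x, feature_names, feature_subset)
    if x.shape[1] == 0:
        raise ValueError("empty feature subset")
    for attempt in range(max_resplits):
        xtr, xte, ytr, yte = train_test_split(
            x, y, test_size=test_fraction, stratify=y,
            random_state=(seed + attempt) % (2**31 - 1))
        if len(np.unique(ytr)) >= 2:
            break
    else:
        raise ValueError("could not obtain a two-class training fold")
    clf = make_pipeline(StandardScaler(),
                        SVC(kernel="rbf", C=C, gamma=gamma))
    clf.fit(xtr, ytr)
    return float(clf.score(xte, yte))


def repeated_accuracy(matrix: np.ndarray, labels: np.ndarray,
                      feature_subset: list | None = None,
                      feature_names: list | None = None,
                      n_reps: int = 30, seed: int = 0,
                      **svm_kwargs) -> AccuracyDistribution:
    """Accuracy distribution over ``n_reps`` independent 70/30 splits."""
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                 for s in ss.spawn(n_reps)]
    accs = [train_gaussian_svm(matrix, labels, feature_subset, feature_names,
                               seed=s, **svm_kwargs) for s in rep_seeds]
    return AccuracyDistribution(np.array(accs),
                                list(feature_subset or feature_names or []),
                                rep_seeds)


def compare_distributions(a: AccuracyDistribution | np.ndarray,
                          b: AccuracyDistribution | np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two accuracy samples."""
    xa = a.accuracies if isinstance(a, AccuracyDistribution) else np.asarray(a)
    xb = b.accuracies if isinstance(b, AccuracyDistribution) else np.asarray(b)
    return float(ranksums(xa, xb).pvalue)
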