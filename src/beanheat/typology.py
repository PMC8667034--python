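"""Water-use typology discovery: standardization, Ward clustering, PCA and
a Monte-Carlo between-group permutation test.

Genotypes are clustered on their standardized trait profiles with Ward's
minimum-variance criterion on Euclidean distances (the squared-merge-cost
"Ward.D2" convention, as implemented by scipy). The number of groups is
chosen by maximum mean silhouette rather than fixed a priori. Group
separation is quantified by the between-group fraction of total variance
(between-group inertia ratio) and tested by random relabeling that
preserves group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import silhouette_score


class TypologyError(ValueError):
    pass


def standardize_traits(df: pd.DataFrame, traits: list[str] | None = None,
                       ddof: int = 1) -> pd.DataFrame:
    """Center each trait to mean 0 and scale to sd 1 (sample sd by default).

    Constant traits carry no distance information and are dropped with a
    warning.
    """
    if traits is None:
        traits = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    out = {}
    for t in traits:
        v = df[t].to_numpy(dtype=float)
        sd = v.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"trait {t!r} is constant; dropped from the matrix",
                          stacklevel=2)
            continue
        out[t] = (v - v.mean()) / sd
    if not out:
        raise TypologyError("no non-constant traits to standardize")
    return pd.DataFrame(out, index=df.index)


def ward_cluster(matrix: np.ndarray | pd.DataFrame, k: int):
    """Ward/Euclidean agglomerative clustering cut at k groups.

    Returns (labels, linkage matrix). Labels are 1..k in scipy's fcluster
    numbering; merge heights are nondecreasing by Ward's criterion.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not (1 <= k <= n):
        raise TypologyError(f"k must lie in 1..{n}, got {k}")
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


@dataclass
class KSelection:
    k: int
    silhouettes: dict[int, float]
    weak_structure: bool = False


def select_k(matrix: np.ndarray | pd.DataFrame, kmax: int = 8,
             weak_threshold: float = 0.25) -> KSelection:
    """Choose the cluster count by maximum mean silhouette over k = 2..kmax.

    The full silhouette profile is returned; a best silhouette below
    ``weak_threshold`` marks the partition as weak structure.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    kmax = min(kmax, n - 1)
    if kmax < 2:
        raise TypologyError("need at least 3 observations to select k")
    sil: dict[int, float] = {}
    for k in range(2, kmax + 1):
        labels, _ = ward_cluster(X, k)
        sil[k] = float(silhouette_score(X, labels, metric="euclidean"))
    best = max(sil, key=lambda k: (sil[k], -k))
    return KSelection(k=best, silhouettes=sil,
                      weak_structure=sil[best] < weak_threshold)


@dataclass
class PCAResult:
    scores: np.ndarray            # (n, k) component scores per genotype
    loadings: np.ndarray          # (k, p) trait loadings per component
    explained_variance_ratio: np.ndarray
    traits: list[str] = field(default_factory=list)


def pca(matrix: np.ndarray | pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of the (standardized) trait matrix."""
    traits = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else []
    X = np.asarray(matrix, dtype=float)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(scores=scores, loadings=model.components_,
                     explained_variance_ratio=model.explained_variance_ratio_,
                     traits=traits)


def between_group_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """Between-group sum of squares over total sum of squares."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    if total == 0:
        raise TypologyError("zero total variance")
    between = 0.0
    for g in np.unique(labels):
        sub = X[labels == g]
        if sub.shape[0] == 0:
            raise TypologyError("empty group")
        d = sub.mean(axis=0) - grand
        between += sub.shape[0] * float(d @ d)
    return between / total


@dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    seed: int
    null_distribution: np.ndarray | None = None


def between_group_test(matrix: np.ndarray | pd.DataFrame, labels,
                       n_permutations: int = 999, seed: int = 0,
                       keep_null: bool = False) -> PermutationTestResult:
    """Monte-Carlo permutation test of group separation.

    The observed statistic is the between-group inertia ratio on the
    standardized matrix; the null distribution comes from ``n_permutations``
    random relabelings preserving group sizes, and
    p = (1 + #{perm ≥ observed}) / (N + 1), so p ∈ [1/(N+1), 1].
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise TypologyError("labels must match matrix rows")
    obs = between_group_ratio(X, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = between_group_ratio(X, rng.permutation(labels))
    p = (1.0 + np.count_nonzero(null >= obs)) / (n_permutations + 1.0)
    return PermutationTestResult(
        statistic=obs, n_permutations=n_permutations, p_value=float(p),
        seed=seed, null_distribution=null if keep_null else None,
    )
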