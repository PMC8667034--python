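import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from beanheat.typology import (
    TypologyError,
    between_group_ratio,
    between_group_test,
    pca,
    select_k,
    standardize_traits,
    ward_cluster,
)


def test_standardize_columns_centered_scaled(rng):
    df = pd.DataFrame(rng.normal(5, 3, size=(40, 4)), columns=list("abcd"))
    X = standardize_traits(df)
    np.testing.assert_allclose(X.mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(X.std(ddof=1), 1.0, rtol=1e-12)
    # idempotent on already-standardized input
    np.testing.assert_allclose(standardize_traits(X).to_numpy(),
                               X.to_numpy(), atol=1e-12)


def test_standardize_drops_constant_with_warning(rng):
    df = pd.DataFrame({"a": rng.normal(size=10), "b": np.full(10, 3.0)})
    with pytest.warns(UserWarning, match="'b'"):
        X = standardize_traits(df)
    assert list(X.columns) == ["a"]


def _two_blobs(rng, n=20, sep=8.0):
    X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(sep, 1, (n, 3))])
    truth = np.repeat([0, 1], n)
    return X, truth


def test_ward_separates_two_clouds(rng):
    X, truth = _two_blobs(rng)
    labels, Z = ward_cluster(X, 2)
    assert adjusted_rand_score(truth, labels) == 1.0
    # merge heights nondecreasing
    assert np.all(np.diff(Z[:, 2]) >= -1e-12)


def test_ward_singletons_and_bad_k(rng):
    X = rng.normal(size=(6, 2))
    labels, _ = ward_cluster(X, 6)
    assert len(set(labels)) == 6
    with pytest.raises(TypologyError):
        ward_cluster(X, 7)


def test_ward_row_order_invariance(rng):
    X, _ = _two_blobs(rng, n=10)
    labels, _ = ward_cluster(X, 2)
    perm = rng.permutation(X.shape[0])
    labels_p, _ = ward_cluster(X[perm], 2)
    assert adjusted_rand_score(labels[perm], labels_p) == 1.0


def test_select_k_three_blobs(rng):
    X = np.vstack([rng.normal(c, 0.5, (15, 3)) for c in (0.0, 6.0, 12.0)])
    sel = select_k(X, kmax=6)
    assert sel.k == 3
    assert not sel.weak_structure


def test_select_k_weak_structure_flag(rng):
    X = rng.normal(size=(120, 5))
    sel = select_k(X, kmax=6)
    assert sel.weak_structure


def test_select_k_profile_matches_silhouette_oracle(rng):
    X = np.vstack([rng.normal(0, 1, (12, 2)), rng.normal(5, 1, (12, 2))])
    sel = select_k(X, kmax=5)
    for k, s in sel.silhouettes.items():
        labels, _ = ward_cluster(X, k)
        assert s == pytest.approx(silhouette_score(X, labels), rel=1e-12)


def test_pca_rank1_and_reconstruction(rng):
    u = rng.normal(size=20)
    X = np.outer(u, [1.0, 2.0, -1.0])
    res = pca(X)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
    # full reconstruction from all components
    Xc = X - X.mean(axis=0)
    np.testing.assert_allclose(res.scores @ res.loadings, Xc, atol=1e-10)
    # loadings orthonormal, fractions sum to 1, scores uncorrelated
    np.testing.assert_allclose(res.loadings @ res.loadings.T,
                               np.eye(res.loadings.shape[0]), atol=1e-10)


def test_pca_variance_fractions_and_score_orthogonality(rng):
    X = rng.normal(size=(50, 4))
    res = pca(X)
    assert np.sum(res.explained_variance_ratio) == pytest.approx(1.0, abs=1e-10)
    cov = np.cov(res.scores, rowvar=False)
    np.testing.assert_allclose(cov - np.diag(np.diag(cov)),
                               np.zeros_like(cov), atol=1e-10)


def test_between_group_ratio_oracle(rng):
    """Statistic equals an explicit loop over groups for all relabelings
    of a small two-group set (exhaustive enumeration, n = 6)."""
    X = rng.normal(size=(6, 3))
    for combo in itertools.combinations(range(6), 3):
        labels = np.zeros(6, dtype=int)
        labels[list(combo)] = 1
        grand = X.mean(axis=0)
        total = ((X - grand) ** 2).sum()
        between = 0.0
        for g in (0, 1):
            sub = X[labels == g]
            between += len(sub) * ((sub.mean(axis=0) - grand) ** 2).sum()
        assert between_group_ratio(X, labels) == pytest.approx(
            between / total, rel=1e-12)


def test_permutation_p_bounds_and_separated_groups(rng):
    X, truth = _two_blobs(rng, n=10)
    res = between_group_test(X, truth, n_permutations=199, seed=1)
    assert res.p_value == pytest.approx(1.0 / 200.0)
    assert 0.0 < res.statistic <= 1.0


def test_permutation_statistic_in_unit_interval_and_errors(rng):
    X = rng.normal(size=(12, 2))
    labels = np.repeat([0, 1, 2], 4)
    res = between_group_test(X, labels, n_permutations=99, seed=0)
    assert 0.0 <= res.statistic <= 1.0
    assert 1.0 / 100.0 <= res.p_value <= 1.0
    with pytest.raises(TypologyError):
        between_group_test(X, labels[:-1], 9, 0)
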