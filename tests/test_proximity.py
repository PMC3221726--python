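import numpy as np
import pytest

from stepclf.io import DataError
from stepclf.proximity import (ProximityView, closeness_ranks, fit_proximity_forest,
                               proximity, proximity_from_leaves,
                               proximity_to_training, train_proximity_matrix)


def brute_force_proximity(model, X_a, X_b):
    """Oracle: count shared terminal nodes tree by tree, with explicit loops."""
    out = np.zeros((len(X_a), len(X_b)))
    for tree in model.forest.estimators_:
        la = tree.apply(np.asarray(X_a, dtype=float))
        lb = tree.apply(np.asarray(X_b, dtype=float))
        for i in range(len(X_a)):
            for j in range(len(X_b)):
                if la[i] == lb[j]:
                    out[i, j] += 1.0
    return out / model.n_trees


def test_single_tree_proximities_are_zero_or_one(toy_blobs):
    X, y = toy_blobs
    model = fit_proximity_forest(X, y, n_trees=1, seed=0)
    values = train_proximity_matrix(model)
    assert set(np.unique(values)) <= {0.0, 1.0}


def test_leaf_indices_deterministic(toy_blobs):
    X, y = toy_blobs
    a = fit_proximity_forest(X, y, n_trees=25, seed=7)
    b = fit_proximity_forest(X, y, n_trees=25, seed=7)
    assert np.array_equal(a.train_leaves, b.train_leaves)


def test_shared_leaf_fraction_example():
    # four trees, three agreeing terminal positions -> S = 0.75
    leaves_a = np.array([[1, 4, 2, 9]])
    leaves_b = np.array([[1, 4, 2, 7]])
    assert proximity_from_leaves(leaves_a, leaves_b)[0, 0] == 0.75


def test_proximity_matches_brute_force_and_is_symmetric(toy_blobs):
    X, y = toy_blobs
    model = fit_proximity_forest(X, y, n_trees=30, seed=1, min_samples_leaf=2)
    values = train_proximity_matrix(model)
    assert np.allclose(values, brute_force_proximity(model, X, X))
    assert np.allclose(values, values.T)
    assert np.allclose(np.diag(values), 1.0)
    assert proximity(model, X[3], X[17]) == pytest.approx(values[3, 17])


def test_within_class_proximity_exceeds_between_class(toy_blobs):
    X, y = toy_blobs
    model = fit_proximity_forest(X, y, n_trees=200, seed=0)
    values = train_proximity_matrix(model)
    same = values[np.ix_(y == "a", y == "a")]
    cross = values[np.ix_(y == "a", y == "b")]
    assert np.median(same) > np.median(cross)


def test_monotone_transform_leaves_proximities_unchanged(toy_blobs):
    """Trees split on thresholds, so a strictly increasing transform of a
    continuous feature induces the same sample partitions at every node."""
    X, y = toy_blobs
    before = train_proximity_matrix(fit_proximity_forest(X, y, n_trees=40, seed=5))
    Xt = X.copy()
    Xt[:, 0] = Xt[:, 0] ** 3 + 2.0 * Xt[:, 0]
    after = train_proximity_matrix(fit_proximity_forest(Xt, y, n_trees=40, seed=5))
    assert np.array_equal(before, after)


def test_closeness_ranks_are_a_permutation_with_index_tiebreak():
    values = np.array([0.5, 0.9, 0.5, 0.1])
    ranks = closeness_ranks(values)
    assert sorted(ranks) == [1, 2, 3, 4]
    assert ranks[1] == 1          # largest proximity
    assert ranks[0] == 2 and ranks[2] == 3  # tie broken by ascending index
    assert closeness_ranks(values, first=3)[3] == 1  # forced self rank


def test_rank_oracle_against_independent_sort():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(2, 15)
        values = rng.choice([0.0, 0.25, 0.5, 1.0], size=n)  # force ties
        ranks = closeness_ranks(values)
        order = sorted(range(n), key=lambda j: (-values[j], j))
        expected = np.empty(n, dtype=int)
        expected[order] = np.arange(1, n + 1)
        assert np.array_equal(ranks, expected)


def test_proximity_view_reference_handling(toy_blobs):
    X, y = toy_blobs
    model = fit_proximity_forest(X[:20], y[:20], n_trees=20, seed=2)
    view = proximity_to_training(model, X[20:25])
    assert view.values.shape == (5, 20)
    # reference of size 1 -> every query's rank vector is [1]
    assert np.array_equal(view.ranks([4]), np.ones((5, 1), dtype=int))
    # ranks within a subset are a permutation of 1..|subset|
    sub = [0, 3, 7, 11]
    ranks = view.ranks(sub)
    assert all(sorted(row) == [1, 2, 3, 4] for row in ranks)
    assert view.rank_of(0, 3, sub) == ranks[0, 1]
    with pytest.raises(DataError):
        view.ranks([])


def test_forest_validation(toy_blobs):
    X, y = toy_blobs
    with pytest.raises(ValueError):
        fit_proximity_forest(X, y, n_trees=0)
    with pytest.raises(DataError):
        fit_proximity_forest(X[:3], np.array(["a", "a", "a"]), n_trees=5)


def test_clinical_space_has_more_zero_proximities_than_molecular():
    """Low-dimensional clinical designs produce many exactly-zero proximities
    while high-dimensional molecular designs produce almost none."""
    from stepclf.io import ClinicalEncoder
    from stepclf.synthetic import GeneratorConfig, generate

    zeros_c, zeros_m = [], []
    for seed in (0, 1, 2):
        cfg = GeneratorConfig(n_samples=60, n_molecular=200, n_molecular_signal=20,
                              clinical_effect=1.2, molecular_effect=0.8, seed=seed)
        ds, _ = generate(cfg)
        ids = ds.train_ids
        y = ds.labels_for(ids)
        Xc = ClinicalEncoder().fit(ds.clinical).transform(ds.clinical)
        Xm = ds.molecular.values_for(ids)
        off = ~np.eye(len(ids), dtype=bool)
        pc = train_proximity_matrix(fit_proximity_forest(Xc, y, 100, seed))
        pm = train_proximity_matrix(fit_proximity_forest(Xm, y, 100, seed))
        zeros_c.append(np.mean(pc[off] == 0.0))
        zeros_m.append(np.mean(pm[off] == 0.0))
    assert np.mean(zeros_c) > np.mean(zeros_m)
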