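"""Random-forest proximity within a feature space, and closeness ranks.

The similarity between two samples is the fraction of trees of a fitted
forest in which they land in the same terminal node,

    S(x_a, x_b) = (1/T) * sum_i I(Z_ai == Z_bi),

with Z_ai the terminal-node position of x_a in tree i.  Because trees split
on thresholds, S is well defined for mixed-type designs and invariant to
monotone transforms of continuous features.  The proximity *values* have
very different distributions in a low-dimensional clinical space (many exact
zeros) and a high-dimensional molecular space (hardly any), so downstream
scores use only closeness ranks (1 = most proximal), never the raw values.

Forests here are classification forests fit on the true training labels
(supervised proximity); they are separate objects from the classifier
plug-ins and exist purely as the similarity source.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import DataError


@dataclasses.dataclass
class ProximityModel:
    """A fitted forest plus the recorded training-sample leaf indices."""

    forest: RandomForestClassifier
    train_leaves: np.ndarray  # (n_train, T)

    @property
    def n_trees(self) -> int:
        return self.train_leaves.shape[1]

    @property
    def n_train(self) -> int:
        return self.train_leaves.shape[0]

    def leaf_indices(self, X: np.ndarray) -> np.ndarray:
        """Terminal-node position of each row of X in each tree, shape (m, T)."""
        return self.forest.apply(np.asarray(X, dtype=float))


def fit_proximity_forest(X: np.ndarray, y: np.ndarray, n_trees: int = 500,
                         seed: int = 0, min_samples_leaf: int = 5,
                         **tree_kwargs) -> ProximityModel:
    """Fit a classification forest to be used as a proximity source.

    ``min_samples_leaf`` acts as the bandwidth of the similarity: fully grown
    trees isolate isolated wrong-labelled points into singleton leaves, which
    makes new samples near them share leaves with the surrounding bulk
    instead, erasing exactly the local-error structure the downstream scores
    look for.  A modest minimum leaf size keeps leaves as small mixed
    neighborhoods.
    """
    if n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {n_trees}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise DataError("need at least 2 samples to fit a proximity forest")
    if len(np.unique(y)) < 2:
        raise DataError("need two classes to fit a proximity forest")
    if not np.isfinite(X).all():
        raise DataError("design matrix has non-finite values; impute upstream")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1,
                                    min_samples_leaf=min_samples_leaf, **tree_kwargs)
    forest.fit(X, y)
    return ProximityModel(forest=forest, train_leaves=forest.apply(X))


def proximity_from_leaves(leaves_a: np.ndarray, leaves_b: np.ndarray,
                          chunk: int = 64) -> np.ndarray:
    """Pairwise shared-leaf fractions, shape (len(a), len(b))."""
    leaves_a = np.asarray(leaves_a)
    leaves_b = np.asarray(leaves_b)
    out = np.empty((leaves_a.shape[0], leaves_b.shape[0]))
    for start in range(0, leaves_a.shape[0], chunk):
        block = leaves_a[start:start + chunk]
        out[start:start + chunk] = (
            block[:, None, :] == leaves_b[None, :, :]).mean(axis=2)
    return out


def proximity(model: ProximityModel, xa: np.ndarray, xb: np.ndarray) -> float:
    """S(xa, xb) for a single pair of feature vectors."""
    la = model.leaf_indices(np.atleast_2d(xa))
    lb = model.leaf_indices(np.atleast_2d(xb))
    return float((la[0] == lb[0]).mean())


def train_proximity_matrix(model: ProximityModel) -> np.ndarray:
    """Training-set self-proximity matrix (symmetric, unit diagonal)."""
    return proximity_from_leaves(model.train_leaves, model.train_leaves)


def closeness_ranks(values: np.ndarray, first: int | None = None) -> np.ndarray:
    """Closeness ranks 1..n of one proximity row (1 = most proximal).

    Ties are broken by ascending reference index, so ranks are a
    deterministic permutation.  ``first`` forces that reference index to
    rank 1 regardless of value (used to give a training sample rank 1
    against itself).
    """
    values = np.asarray(values, dtype=float)
    key = values.copy()
    if first is not None:
        key[first] = np.inf
    order = np.lexsort((np.arange(len(key)), -key))
    ranks = np.empty(len(key), dtype=int)
    ranks[order] = np.arange(1, len(key) + 1)
    return ranks


@dataclasses.dataclass
class ProximityView:
    """Proximities of a query set against the training set, plus ranks.

    ``values[q, t]`` is S(query q, training sample t).  Ranks are computed
    within a stated reference subset of training samples; by default the
    whole training set.
    """

    values: np.ndarray  # (n_query, n_train)
    query_ids: Sequence | None = None
    train_ids: Sequence | None = None

    def ranks(self, reference: Sequence[int] | None = None) -> np.ndarray:
        """Closeness ranks (rows: queries) within the reference subset.

        Each row is a permutation of 1..|reference|; ties broken by
        ascending training index.
        """
        ref = (np.arange(self.values.shape[1]) if reference is None
               else np.asarray(list(reference), dtype=int))
        if ref.size == 0:
            raise DataError("empty reference subset for proximity ranks")
        sub = self.values[:, ref]
        out = np.empty_like(sub, dtype=int)
        for q in range(sub.shape[0]):
            out[q] = closeness_ranks(sub[q])
        return out

    def rank_of(self, query: int, train: int,
                reference: Sequence[int] | None = None) -> int:
        ref = (list(range(self.values.shape[1])) if reference is None
               else list(reference))
        pos = ref.index(train)
        return int(self.ranks(ref)[query, pos])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.query_ids, columns=self.train_ids)


def proximity_to_training(model: ProximityModel, X_query: np.ndarray,
                          query_ids: Sequence | None = None,
                          train_ids: Sequence | None = None) -> ProximityView:
    """Proximity of each query sample to each training sample."""
    if model.n_train == 0:
        raise DataError("proximity model has an empty training set")
    leaves_q = model.leaf_indices(X_query)
    return ProximityView(values=proximity_from_leaves(leaves_q, model.train_leaves),
                         query_ids=query_ids, train_ids=train_ids)
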