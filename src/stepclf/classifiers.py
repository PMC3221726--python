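"""Pluggable classifiers and the cross-validated training-set predictions.

The two-stage procedure starts by asking, for every training sample, whether
the clinical-space classifier and the molecular-space classifier get it
right.  Those correct/wrong flags are the raw material of the
re-classification score, so they must estimate *generalization* behaviour:
we therefore use out-of-fold predictions (every sample predicted by a model
that never saw it), not resubstitution, which with forests would be nearly
error-free and degenerate.

A classifier plug-in is anything with sklearn-style ``fit(X, y)`` /
``predict(X)``; built-ins are registered by name so they can be named on the
command line:

* ``random_forest``      -- either space; handles integer-coded categoricals;
* ``penalized_logistic`` -- ridge-penalized logistic regression on
  standardized features;
* ``pls_rf``             -- supervised partial-least-squares reduction of the
  molecular matrix followed by a forest on the latent components.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .io import DataError, LabeledDataset, ClinicalEncoder

logger = logging.getLogger("stepclf")

SPACES = ("clinical", "molecular")


@dataclasses.dataclass
class ClassifierSpec:
    """A named classifier bound to a feature space, with a tuning grid.

    A single-point (or empty) grid bypasses inner-CV tuning entirely.
    """

    name: str
    space: str
    grid: Mapping[str, Sequence] = dataclasses.field(default_factory=dict)
    tuning_folds: int = 5

    def __post_init__(self) -> None:
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}, got {self.space!r}")
        if self.name not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.name!r}; "
                             f"registered: {sorted(CLASSIFIERS)}")
        if self.grid_size > 1 and self.tuning_folds < 2:
            raise ValueError("tuning folds must be >= 2 when the grid has > 1 point")

    @property
    def grid_size(self) -> int:
        size = 1
        for values in self.grid.values():
            if len(values) == 0:
                raise ValueError("empty list in hyperparameter grid")
            size *= len(values)
        return size

    def grid_points(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


# ---------------------------------------------------------------------------
# built-in classifiers
# ---------------------------------------------------------------------------


class PLSRandomForest(BaseEstimator, ClassifierMixin):
    """PLS dimension reduction followed by a random forest on the components.

    The binary labels are coded -1/+1 for the PLS regression; the forest is
    then fit on the latent scores.  Requested components beyond
    ``min(n_samples - 1, n_features)`` are clipped with a warning.
    """

    def __init__(self, n_components: int = 2, n_estimators: int = 200,
                 random_state: int | None = None):
        self.n_components = n_components
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSRandomForest":
        X = np.asarray(X, dtype=float)
        max_comp = min(X.shape[0] - 1, X.shape[1])
        k = self.n_components
        if k > max_comp:
            warnings.warn(
                f"pls_rf: requested {k} components exceeds min(n-1, p)={max_comp}; clipped",
                stacklevel=2)
            k = max_comp
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        target = y_idx.astype(float) * 2.0 - 1.0
        self.pls_ = PLSRegression(n_components=k, scale=True)
        self.pls_.fit(X, target)
        scores = self.pls_.transform(X)
        self.rf_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state, n_jobs=1)
        self.rf_.fit(scores, y_idx)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.rf_.predict(self.pls_.transform(np.asarray(X, dtype=float)))]


def _build_random_forest(seed: int, n_estimators: int = 200,
                         max_features: str | float = "sqrt", **kw):
    return RandomForestClassifier(n_estimators=n_estimators, max_features=max_features,
                                  random_state=seed, n_jobs=1, **kw)


def _build_penalized_logistic(seed: int, C: float = 1.0, **kw):
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, max_iter=2000, random_state=seed, **kw),
    )


def _build_pls_rf(seed: int, n_components: int = 2, n_estimators: int = 200, **kw):
    return PLSRandomForest(n_components=n_components, n_estimators=n_estimators,
                           random_state=seed, **kw)


CLASSIFIERS: dict[str, Callable] = {
    "random_forest": _build_random_forest,
    "penalized_logistic": _build_penalized_logistic,
    "pls_rf": _build_pls_rf,
}

#: small default grids; single-point grids skip tuning
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {},
    "penalized_logistic": {"C": [0.1, 1.0, 10.0]},
    "pls_rf": {"n_components": [2, 3]},
}


def make_spec(name: str, space: str, grid: Mapping[str, Sequence] | None = None,
              tuning_folds: int = 5) -> ClassifierSpec:
    if grid is None:
        grid = DEFAULT_GRIDS.get(name, {})
    return ClassifierSpec(name=name, space=space, grid=grid, tuning_folds=tuning_folds)


def build_classifier(spec: ClassifierSpec, seed: int, params: Mapping | None = None):
    params = dict(params or {})
    return CLASSIFIERS[spec.name](seed, **params)


# ---------------------------------------------------------------------------
# cross-validated out-of-fold predictions
# ---------------------------------------------------------------------------


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> StratifiedKFold:
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise DataError("cannot form stratified folds: a class has < 2 samples")
    eff = min(n_folds, min_count)
    if eff < n_folds:
        logger.info("reducing folds from %d to %d (smallest class has %d samples)",
                    n_folds, eff, min_count)
    return StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed)


def tune(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, seed: int) -> dict:
    """Pick grid point maximizing mean inner-CV accuracy (ties: first point)."""
    points = spec.grid_points()
    if len(points) == 1:
        return points[0]
    skf = _stratified_folds(y, spec.tuning_folds, seed)
    best, best_acc = points[0], -1.0
    for params in points:
        accs = []
        for tr, te in skf.split(X, y):
            est = build_classifier(spec, seed, params)
            est.fit(X[tr], y[tr])
            accs.append(float(np.mean(est.predict(X[te]) == y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best, best_acc = params, acc
    return best


def oof_predictions(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                    folds: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold predicted labels for every row of ``X``.

    Hyperparameters (when the grid has > 1 point) are tuned by inner CV
    within each outer training fold.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = _stratified_folds(y, folds, seed)
    pred = np.empty_like(y)
    for tr, te in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            raise DataError("training fold contains a single class")
        params = tune(X[tr], y[tr], spec, seed)
        est = build_classifier(spec, seed, params)
        est.fit(X[tr], y[tr])
        pred[te] = est.predict(X[te])
    return pred


def fit_predict_cv(dataset: LabeledDataset, spec: ClassifierSpec,
                   outer_folds: int = 10, seed: int = 0):
    """Out-of-fold predictions for the dataset's training samples.

    For the clinical space the encoder (category codes and imputation
    statistics) is refit on each outer training fold, so a held-out sample
    never influences the design matrix rows of other held-out samples.
    Returns a pandas-free dict {sample_id: predicted label}.
    """
    ids = dataset.train_ids
    if not ids:
        raise DataError("dataset has no labeled training samples")
    y = dataset.labels_for(ids)
    skf = _stratified_folds(y, outer_folds, seed)

    if spec.space == "molecular":
        if dataset.molecular is None:
            raise DataError("molecular classifier requested but no molecular data")
        X = dataset.molecular.values_for(ids)
        pred = oof_from_folds(X, y, spec, list(skf.split(np.zeros(len(y)), y)), seed)
    else:
        table = dataset.clinical
        pred = np.empty_like(y)
        for tr, te in skf.split(np.zeros(len(y)), y):
            enc = ClinicalEncoder().fit(table, [ids[i] for i in tr])
            X = enc.transform(table, ids)
            params = tune(X[tr], y[tr], spec, seed)
            est = build_classifier(spec, seed, params)
            est.fit(X[tr], y[tr])
            pred[te] = est.predict(X[te])
    return dict(zip(ids, pred))


def oof_from_folds(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                   folds: Sequence[tuple[np.ndarray, np.ndarray]], seed: int) -> np.ndarray:
    """Out-of-fold predictions over an explicit fold list (shared-fold runs)."""
    pred = np.empty_like(np.asarray(y))
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2:
            raise DataError("training fold contains a single class")
        params = tune(X[tr], y[tr], spec, seed)
        est = build_classifier(spec, seed, params)
        est.fit(X[tr], y[tr])
        pred[te] = est.predict(X[te])
    return pred


# ---------------------------------------------------------------------------
# training state
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TrainingState:
    """Correct/wrong flags of every training sample in both feature spaces.

    ``ncw``/``ncr`` count clinically wrong/right samples, ``ngw``/``ngr``
    their molecular ("genomic") counterparts.  The global neighborhood size
    is ``K = min(NCW, NCR, NGW, NGR)``, falling back to 1 when a perfect
    classification would set it to 0.
    """

    y: np.ndarray
    clinical_pred: np.ndarray
    molecular_pred: np.ndarray
    clinical_correct: np.ndarray
    molecular_correct: np.ndarray
    ncw: int
    ncr: int
    ngw: int
    ngr: int
    k: int

    @property
    def n_train(self) -> int:
        return len(self.y)


def choose_k(ncw: int, ncr: int, ngw: int, ngr: int) -> int:
    """The fixed neighborhood size: min of the four counts, at least 1."""
    k = min(ncw, ncr, ngw, ngr)
    return k if k > 0 else 1


def build_training_state(y: np.ndarray, clinical_pred: np.ndarray,
                         molecular_pred: np.ndarray) -> TrainingState:
    y = np.asarray(y)
    clinical_pred = np.asarray(clinical_pred)
    molecular_pred = np.asarray(molecular_pred)
    if not (len(y) == len(clinical_pred) == len(molecular_pred)):
        raise DataError("prediction vectors must cover all training samples")
    cc = clinical_pred == y
    mc = molecular_pred == y
    ncr, ncw = int(cc.sum()), int((~cc).sum())
    ngr, ngw = int(mc.sum()), int((~mc).sum())
    return TrainingState(
        y=y, clinical_pred=clinical_pred, molecular_pred=molecular_pred,
        clinical_correct=cc, molecular_correct=mc,
        ncw=ncw, ncr=ncr, ngw=ngw, ngr=ngr, k=choose_k(ncw, ncr, ngw, ngr),
    )
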