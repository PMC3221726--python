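"""The full two-stage procedure: accuracy-vs-reclassification curves under
repeated cross-validation, RS cut-point derivation, and prospective
one-at-a-time classification.

In evaluation mode every sample has both data types, so we can *simulate*
the economics: within each CV fold the clinical classifier labels every test
sample, the RS ranks them, and the top ``ceil(p * m)`` samples are
re-labelled by the molecular classifier.  Sweeping the proportion ``p`` from
0 to 1 traces a curve whose left end is the clinical-only CV accuracy and
whose right end is the molecular-only CV accuracy (identical folds and
seeds), showing how quickly the cheap-first procedure approaches the
expensive classifier.

Within each fold the correct/wrong flags that feed the RS come from
out-of-fold predictions *inside the training part*; test labels never enter
the RS.

Prospectively, a chosen proportion is converted once into an RS cut point
(the matching empirical quantile on the study data); a new sample whose RS
stays below the cut point keeps its clinical label, otherwise molecular
measurement is advised.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from .classifiers import ClassifierSpec, TrainingState, build_classifier, \
    build_training_state, oof_from_folds, tune
from .io import ClinicalEncoder, ClinicalTable, DataError, LabeledDataset, MolecularMatrix
from .proximity import ProximityModel, fit_proximity_forest
from .rs import RSResult, rs_for_test_set

logger = logging.getLogger("stepclf")

DEFAULT_PROPORTIONS = tuple(np.round(np.linspace(0.0, 1.0, 11), 2))


# ---------------------------------------------------------------------------
# evaluation curves
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FoldRecord:
    """Everything needed to replay one CV fold's two-stage decisions."""

    repeat: int
    fold: int
    test_ids: list
    y_true: np.ndarray
    clinical_pred: np.ndarray
    molecular_pred: np.ndarray
    rs: np.ndarray

    def reclassified(self, proportion: float) -> np.ndarray:
        """Positional indices of test samples re-classified at ``proportion``
        (the top ceil(p * m) by RS; ties broken by ascending index)."""
        m = len(self.rs)
        k = math.ceil(proportion * m)
        order = np.lexsort((np.arange(m), -self.rs))
        return order[:k]

    def stepwise_pred(self, proportion: float) -> np.ndarray:
        pred = self.clinical_pred.copy()
        top = self.reclassified(proportion)
        pred[top] = self.molecular_pred[top]
        return pred


def _balanced_accuracy(y: np.ndarray, pred: np.ndarray) -> float:
    classes = np.unique(y)
    return float(np.mean([np.mean(pred[y == c] == c) for c in classes]))


@dataclasses.dataclass
class AccuracyCurve:
    """Accuracy (mean +/- sd) at each re-classification proportion.

    With several CV repeats the spread is across repeats (folds pooled
    within a repeat); with a single repeat it is across folds.  Balanced
    accuracy is reported alongside plain accuracy since class imbalance is
    common in the intended applications.
    """

    proportions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    balanced_mean: np.ndarray
    balanced_sd: np.ndarray
    records: list[FoldRecord]
    molecular_name: str = ""

    def accuracy_at(self, proportion: float) -> float:
        i = int(np.argmin(np.abs(self.proportions - proportion)))
        if not math.isclose(self.proportions[i], proportion, abs_tol=1e-9):
            raise KeyError(f"proportion {proportion} not on the curve grid")
        return float(self.mean[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "proportion": self.proportions,
            "accuracy_mean": self.mean,
            "accuracy_sd": self.sd,
            "balanced_accuracy_mean": self.balanced_mean,
            "balanced_accuracy_sd": self.balanced_sd,
            "n_folds": len(self.records),
        })


def _curve_from_records(records: list[FoldRecord], proportions: np.ndarray,
                        name: str) -> AccuracyCurve:
    repeats = sorted({r.repeat for r in records})
    acc = np.empty((len(repeats), len(proportions)))
    bal = np.empty_like(acc)
    for ri, rep in enumerate(repeats):
        recs = [r for r in records if r.repeat == rep]
        for pi, p in enumerate(proportions):
            y = np.concatenate([r.y_true for r in recs])
            pred = np.concatenate([r.stepwise_pred(p) for r in recs])
            acc[ri, pi] = float(np.mean(pred == y))
            bal[ri, pi] = _balanced_accuracy(y, pred)
    if len(repeats) == 1:  # spread across folds instead
        recs = [r for r in records if r.repeat == repeats[0]]
        per_fold = np.array([[float(np.mean(r.stepwise_pred(p) == r.y_true))
                              for p in proportions] for r in recs])
        sd = per_fold.std(axis=0, ddof=1) if len(recs) > 1 else np.zeros(len(proportions))
        per_fold_b = np.array([[_balanced_accuracy(r.y_true, r.stepwise_pred(p))
                                for p in proportions] for r in recs])
        bsd = per_fold_b.std(axis=0, ddof=1) if len(recs) > 1 else np.zeros(len(proportions))
    else:
        sd = acc.std(axis=0, ddof=1)
        bsd = bal.std(axis=0, ddof=1)
    return AccuracyCurve(proportions=proportions, mean=acc.mean(axis=0), sd=sd,
                         balanced_mean=bal.mean(axis=0), balanced_sd=bsd,
                         records=records, molecular_name=name)


def evaluate_curves(
    dataset: LabeledDataset,
    clinical_spec: ClassifierSpec,
    molecular_specs: Sequence[ClassifierSpec],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    repeats: int = 10,
    folds: int = 10,
    seed: int = 0,
    state_folds: int = 10,
    n_trees: int = 500,
    blind_im: bool = False,
    second_stage: str = "molecular",
) -> list[AccuracyCurve]:
    """Accuracy curves for one clinical classifier and several molecular
    plug-ins, sharing folds, the clinical work and the proximity forests.

    ``second_stage='both'`` exposes the variant in which the molecular
    classifier additionally sees the clinical design; the default uses
    molecular data only in the second stage.
    """
    proportions = np.asarray(sorted(proportions), dtype=float)
    if proportions.min() < 0.0 or proportions.max() > 1.0:
        raise ValueError("re-classification proportions must lie in [0, 1]")
    if second_stage not in ("molecular", "both"):
        raise ValueError("second_stage must be 'molecular' or 'both'")
    ids = dataset.train_ids
    if dataset.molecular is None or len(ids) < 4:
        raise DataError("curve evaluation needs labels and molecular data for all samples")
    y = dataset.labels_for(ids)
    Xm_all = dataset.molecular.values_for(ids)

    records: dict[int, list[FoldRecord]] = {s: [] for s in range(len(molecular_specs))}
    for rep in range(repeats):
        rep_seed = seed + 1009 * rep
        skf = clf._stratified_folds(y, folds, rep_seed)
        for fold_i, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
            fold_seed = rep_seed + 17 * fold_i
            enc = ClinicalEncoder().fit(dataset.clinical, [ids[i] for i in tr])
            Xc = enc.transform(dataset.clinical, ids)
            Xc_tr, Xc_te = Xc[tr], Xc[te]
            Xm_tr, Xm_te = Xm_all[tr], Xm_all[te]
            y_tr, y_te = y[tr], y[te]

            inner = list(clf._stratified_folds(y_tr, state_folds, fold_seed)
                         .split(np.zeros(len(y_tr)), y_tr))
            clin_oof = oof_from_folds(Xc_tr, y_tr, clinical_spec, inner, fold_seed)

            prox_c = fit_proximity_forest(Xc_tr, y_tr, n_trees, fold_seed + 1)
            prox_m = fit_proximity_forest(Xm_tr, y_tr, n_trees, fold_seed + 2)

            params = tune(Xc_tr, y_tr, clinical_spec, fold_seed)
            est_c = build_classifier(clinical_spec, fold_seed, params)
            est_c.fit(Xc_tr, y_tr)
            clin_pred = est_c.predict(Xc_te)

            if second_stage == "both":
                Xs_tr, Xs_te = np.hstack([Xm_tr, Xc_tr]), np.hstack([Xm_te, Xc_te])
            else:
                Xs_tr, Xs_te = Xm_tr, Xm_te

            for si, mspec in enumerate(molecular_specs):
                mol_oof = oof_from_folds(Xm_tr, y_tr, mspec, inner, fold_seed)
                state = build_training_state(y_tr, clin_oof, mol_oof)

                mparams = tune(Xs_tr, y_tr, mspec, fold_seed)
                est_m = build_classifier(mspec, fold_seed, mparams)
                est_m.fit(Xs_tr, y_tr)
                mol_pred = est_m.predict(Xs_te)

                blind_rng = (np.random.default_rng(fold_seed + 31 * si + 7)
                             if blind_im else None)
                rs = rs_for_test_set(state, prox_c, prox_m, Xc_te, blind_rng=blind_rng)
                records[si].append(FoldRecord(
                    repeat=rep, fold=fold_i, test_ids=[ids[i] for i in te],
                    y_true=y_te, clinical_pred=clin_pred, molecular_pred=mol_pred,
                    rs=rs.rs))
    return [_curve_from_records(records[si], proportions, molecular_specs[si].name)
            for si in range(len(molecular_specs))]


def evaluate_curve(dataset: LabeledDataset, clinical_spec: ClassifierSpec,
                   molecular_spec: ClassifierSpec, **kwargs) -> AccuracyCurve:
    """Single-plug-in convenience wrapper around :func:`evaluate_curves`."""
    return evaluate_curves(dataset, clinical_spec, [molecular_spec], **kwargs)[0]


def plot_curve(curves: AccuracyCurve | Sequence[AccuracyCurve], path) -> None:
    """Write an accuracy-vs-proportion plot (matplotlib, file-only backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(curves, AccuracyCurve):
        curves = [curves]
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        label = curve.molecular_name or "stepwise"
        ax.errorbar(curve.proportions * 100, curve.mean, yerr=curve.sd,
                    marker="o", capsize=3, label=label)
    ax.set_xlabel("% of samples re-classified with molecular data")
    ax.set_ylabel("accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# cut points
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CutPoint:
    """An RS threshold realizing an intended re-classification proportion."""

    rs_threshold: float
    proportion: float


def derive_cutpoint(rs_values: Sequence[float], proportion: float) -> CutPoint:
    """Empirical-quantile cut point: among the study RS values, exactly
    ``ceil(proportion * n)`` lie at or above the returned threshold."""
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    rs = np.sort(np.asarray(rs_values, dtype=float))[::-1]
    k = math.ceil(proportion * rs.size)
    threshold = np.inf if k == 0 else float(rs[k - 1])
    return CutPoint(rs_threshold=threshold, proportion=proportion)


# ---------------------------------------------------------------------------
# prospective classification
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Decision:
    """Outcome for one prospective sample.

    ``deferred`` means the RS reached the cut point, so molecular measurement
    is advised; the label is then only available once molecular values are
    supplied.  ``flagged`` marks molecular data spent on a non-deferred
    sample (unnecessary cost).
    """

    sample_id: str
    rs: float
    deferred: bool
    label: object | None
    flagged: bool = False

    @property
    def action(self) -> str:
        return "acquire molecular data" if self.deferred and self.label is None \
            else "label"


class StepwiseModel:
    """The fitted two-stage classifier for prospective use.

    ``fit`` trains, on the study data: out-of-fold correct/wrong flags in
    both spaces, the two proximity forests, and the final clinical and
    molecular classifiers.  ``classify`` then scores new samples from their
    clinical values alone and either labels them or defers to molecular
    measurement.
    """

    def __init__(self, clinical_spec: ClassifierSpec, molecular_spec: ClassifierSpec,
                 state_folds: int = 10, n_trees: int = 500, seed: int = 0):
        self.clinical_spec = clinical_spec
        self.molecular_spec = molecular_spec
        self.state_folds = state_folds
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, dataset: LabeledDataset) -> "StepwiseModel":
        ids = dataset.train_ids
        if dataset.molecular is None or not ids:
            raise DataError("training requires labels and molecular data")
        self.train_ids_ = ids
        y = dataset.labels_for(ids)
        self.encoder_ = ClinicalEncoder().fit(dataset.clinical, ids)
        Xc = self.encoder_.transform(dataset.clinical, ids)
        Xm = dataset.molecular.values_for(ids)

        inner = list(clf._stratified_folds(y, self.state_folds, self.seed)
                     .split(np.zeros(len(y)), y))
        clin_oof = oof_from_folds(Xc, y, self.clinical_spec, inner, self.seed)
        mol_oof = oof_from_folds(Xm, y, self.molecular_spec, inner, self.seed)
        self.state_: TrainingState = build_training_state(y, clin_oof, mol_oof)

        self.prox_clinical_: ProximityModel = fit_proximity_forest(
            Xc, y, self.n_trees, self.seed + 1)
        self.prox_molecular_: ProximityModel = fit_proximity_forest(
            Xm, y, self.n_trees, self.seed + 2)

        cparams = tune(Xc, y, self.clinical_spec, self.seed)
        self.clinical_clf_ = build_classifier(self.clinical_spec, self.seed, cparams)
        self.clinical_clf_.fit(Xc, y)
        mparams = tune(Xm, y, self.molecular_spec, self.seed)
        self.molecular_clf_ = build_classifier(self.molecular_spec, self.seed, mparams)
        self.molecular_clf_.fit(Xm, y)
        return self

    def rs_scores(self, table: ClinicalTable) -> RSResult:
        Xc = self.encoder_.transform(table)
        return rs_for_test_set(self.state_, self.prox_clinical_, self.prox_molecular_,
                               Xc, sample_ids=table.sample_ids)

    def classify(self, table: ClinicalTable, cutpoint: CutPoint,
                 molecular: MolecularMatrix | None = None) -> list[Decision]:
        """Classify new samples one at a time from clinical values.

        RS below the cut point -> clinical label.  Otherwise the sample is
        deferred; if its molecular values are present in ``molecular`` the
        second-stage label is produced immediately.  Molecular values
        supplied for a non-deferred sample are used but flagged as an
        unnecessary cost.
        """
        result = self.rs_scores(table)
        Xc = self.encoder_.transform(table)
        clin_labels = self.clinical_clf_.predict(Xc)
        mol_ids = set(molecular.sample_ids) if molecular is not None else set()
        decisions: list[Decision] = []
        n_flagged = 0
        for i, sid in enumerate(table.sample_ids):
            deferred = bool(result.rs[i] >= cutpoint.rs_threshold)
            has_mol = sid in mol_ids
            if deferred:
                label = (self.classify_with_molecular(molecular, [sid])[0]
                         if has_mol else None)
                decisions.append(Decision(sid, float(result.rs[i]), True, label))
            else:
                flagged = has_mol
                n_flagged += flagged
                label = (self.classify_with_molecular(molecular, [sid])[0]
                         if has_mol else clin_labels[i])
                decisions.append(Decision(sid, float(result.rs[i]), False, label,
                                          flagged=flagged))
        n_def = sum(d.deferred for d in decisions)
        logger.info("classified %d sample(s): %d deferred to molecular data (%.1f%%), "
                    "%d flagged for unnecessary molecular measurement",
                    len(decisions), n_def, 100.0 * n_def / max(len(decisions), 1),
                    n_flagged)
        return decisions

    def classify_with_molecular(self, molecular: MolecularMatrix,
                                ids: Sequence[str]) -> np.ndarray:
        """Second-stage labels for deferred samples, once measured."""
        return self.molecular_clf_.predict(molecular.values_for(ids))


def classify_prospective(model: StepwiseModel, table: ClinicalTable,
                         cutpoint: CutPoint,
                         molecular: MolecularMatrix | None = None) -> list[Decision]:
    """Functional alias for :meth:`StepwiseModel.classify`."""
    return model.classify(table, cutpoint, molecular)
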