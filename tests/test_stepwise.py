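import math

import numpy as np
import pytest
from scipy.stats import binom

from stepclf.classifiers import make_spec
from stepclf.io import MolecularMatrix
from stepclf.stepwise import (StepwiseModel, derive_cutpoint, evaluate_curve,
                              evaluate_curves)
from stepclf.synthetic import GeneratorConfig, SubgroupSpec, generate

CLIN_SPEC = make_spec("random_forest", "clinical", {"n_estimators": [50]})
MOL_SPEC = make_spec("random_forest", "molecular", {"n_estimators": [50]})

FAST = dict(repeats=1, folds=3, state_folds=3, n_trees=50)


@pytest.fixture(scope="module")
def small_curve():
    cfg = GeneratorConfig(n_samples=60, n_molecular=40, n_molecular_signal=10,
                          clinical_effect=1.4, molecular_effect=1.0, rho=0.3,
                          subgroups=(SubgroupSpec(1, 0.2, "clinical"),), seed=0)
    dataset, _ = generate(cfg, seed=11)
    curve = evaluate_curve(dataset, CLIN_SPEC, MOL_SPEC,
                           proportions=[0.0, 0.3, 0.6, 1.0], seed=4, **FAST)
    return dataset, curve


def test_endpoints_match_single_platform_predictions_per_fold(small_curve):
    _, curve = small_curve
    for rec in curve.records:
        assert np.array_equal(rec.stepwise_pred(0.0), rec.clinical_pred)
        assert np.array_equal(rec.stepwise_pred(1.0), rec.molecular_pred)
    pooled_y = np.concatenate([r.y_true for r in curve.records])
    clin = np.concatenate([r.clinical_pred for r in curve.records])
    mol = np.concatenate([r.molecular_pred for r in curve.records])
    assert curve.mean[0] == pytest.approx(np.mean(clin == pooled_y))
    assert curve.mean[-1] == pytest.approx(np.mean(mol == pooled_y))


def test_reclassified_counts_and_nesting(small_curve):
    _, curve = small_curve
    for rec in curve.records:
        m = len(rec.rs)
        previous = set()
        for p in (0.0, 0.25, 0.5, 0.75, 1.0):
            chosen = set(rec.reclassified(p))
            assert len(chosen) == math.ceil(p * m)
            assert previous <= chosen  # monotone resource use
            previous = chosen


def test_curve_grid_validation(small_curve):
    dataset, _ = small_curve
    with pytest.raises(ValueError, match="proportions"):
        evaluate_curve(dataset, CLIN_SPEC, MOL_SPEC, proportions=[0.0, 1.2],
                       seed=0, **FAST)
    with pytest.raises(ValueError, match="second_stage"):
        evaluate_curve(dataset, CLIN_SPEC, MOL_SPEC, proportions=[0.0],
                       second_stage="clinical", seed=0, **FAST)


def test_multi_plugin_curves_share_the_clinical_endpoint(small_curve):
    dataset, _ = small_curve
    specs = [MOL_SPEC, make_spec("penalized_logistic", "molecular", {"C": [1.0]})]
    curves = evaluate_curves(dataset, CLIN_SPEC, specs, proportions=[0.0, 1.0],
                             seed=9, **FAST)
    assert curves[0].mean[0] == pytest.approx(curves[1].mean[0])
    assert curves[0].molecular_name == "random_forest"
    assert curves[1].molecular_name == "penalized_logistic"


def test_second_stage_both_variant_runs(small_curve):
    dataset, _ = small_curve
    curve = evaluate_curve(dataset, CLIN_SPEC, MOL_SPEC, proportions=[0.0, 1.0],
                           second_stage="both", seed=9, **FAST)
    assert np.all((0.0 <= curve.mean) & (curve.mean <= 1.0))


def test_accuracy_curve_frame_and_lookup(small_curve):
    _, curve = small_curve
    frame = curve.to_frame()
    assert list(frame["proportion"]) == [0.0, 0.3, 0.6, 1.0]
    assert curve.accuracy_at(0.6) == frame["accuracy_mean"][2]
    with pytest.raises(KeyError):
        curve.accuracy_at(0.45)


def test_cutpoint_quantile_arithmetic():
    rs = np.arange(1.0, 11.0)  # {1..10}
    assert derive_cutpoint(rs, 0.0).rs_threshold > rs.max()
    assert derive_cutpoint(rs, 1.0).rs_threshold <= rs.min()
    cut = derive_cutpoint(rs, 0.3)
    assert np.sum(rs >= cut.rs_threshold) == 3
    with pytest.raises(ValueError):
        derive_cutpoint(rs, 1.5)


@pytest.fixture(scope="module")
def fitted_model(small_curve):
    dataset, _ = small_curve
    model = StepwiseModel(CLIN_SPEC, MOL_SPEC, state_folds=3, n_trees=50, seed=2)
    return dataset, model.fit(dataset)


def test_prospective_proportion_zero_always_labels(fitted_model):
    dataset, model = fitted_model
    study_rs = model.rs_scores(dataset.clinical)
    cut = derive_cutpoint(study_rs.rs, 0.0)
    decisions = model.classify(dataset.clinical, cut)
    assert all(not d.deferred and d.action == "label" for d in decisions)
    assert all(d.label is not None for d in decisions)


def test_prospective_deferral_and_cost_flag(fitted_model):
    dataset, model = fitted_model
    study_rs = model.rs_scores(dataset.clinical)
    cut = derive_cutpoint(study_rs.rs, 0.5)
    decisions = model.classify(dataset.clinical, cut, molecular=dataset.molecular)
    deferred = [d for d in decisions if d.deferred]
    assert deferred and all(d.label is not None for d in deferred)  # fulfilled
    not_deferred = [d for d in decisions if not d.deferred]
    assert not_deferred and all(d.flagged for d in not_deferred)  # cost warning
    # without molecular data, deferral leaves the label pending
    pending = model.classify(dataset.clinical, cut)
    assert any(d.deferred and d.label is None and
               d.action == "acquire molecular data" for d in pending)


def test_prospective_deferral_fraction_tracks_the_intended_proportion(fitted_model):
    """Monitoring check: on 100 fresh samples from the study population the
    deferral count stays inside the 99% binomial band around the proportion
    the cut point was derived for."""
    dataset, model = fitted_model
    study_rs = model.rs_scores(dataset.clinical.subset(dataset.train_ids))
    cut = derive_cutpoint(study_rs.rs, 0.3)
    cfg = GeneratorConfig(n_samples=100, n_molecular=40, n_molecular_signal=10,
                          clinical_effect=1.4, molecular_effect=1.0, rho=0.3,
                          subgroups=(SubgroupSpec(1, 0.2, "clinical"),), seed=0)
    fresh, _ = generate(cfg, seed=77)
    decisions = model.classify(fresh.clinical, cut)
    n_def = sum(d.deferred for d in decisions)
    lo, hi = binom.ppf([0.005, 0.995], 100, 0.3)
    assert lo <= n_def <= hi
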