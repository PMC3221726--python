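import numpy as np
import pytest

from stepclf.io import DataError
from stepclf.rs import (aggregate_rs, clinical_pseudo_nn, g_score_components,
                        g_scores, reclassification_scores)

from _oracles import brute_rs, random_rs_instance


# --- a fully hand-computed 3-train / 1-test micro instance (K = 1) ----------

CLIN3 = np.array([[0.9, 0.5, 0.1]])
MOL3 = np.array([[1.0, 0.8, 0.2], [0.8, 1.0, 0.4], [0.2, 0.4, 1.0]])
C_OK3 = np.array([True, False, True])
M_OK3 = np.array([True, True, False])


def test_hand_computed_micro_instance():
    res = reclassification_scores(CLIN3, MOL3, C_OK3, M_OK3, k=1)
    assert res.right[0] == 2.0      # nearest correct: rank 1, G = 3 - 1 = 2
    assert res.wrong[0] == 4.0      # nearest wrong: rank 2, G = 2
    assert res.rs[0] == -2.0


def test_g_micro_values():
    g_r, g_w = g_score_components(MOL3, M_OK3, k=1)
    assert list(g_r) == [1.0, 1.0, 2.0]   # self at rank 1 for correct samples
    assert list(g_w) == [3.0, 3.0, 1.0]   # self at rank 1 for the wrong sample
    assert list(g_scores(MOL3, M_OK3, k=1)) == [2.0, 2.0, -1.0]


# --- weighted-rank examples --------------------------------------------------

def test_pseudo_nn_weighted_rank_examples():
    # nearest correct neighbor at global rank 1 -> C = 1;
    # second-closest correct neighbor at global rank 5 -> C = 5/2
    prox = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
    correct = np.array([True, False, False, False, True, True])
    ctx = clinical_pseudo_nn(prox, correct, k=2)
    assert list(ctx.cr_idx) == [0, 4]
    assert list(ctx.rank_r) == [1, 5]
    assert list(ctx.c_r) == [1.0, 2.5]
    assert list(ctx.cw_idx) == [1, 2]
    assert list(ctx.c_w) == [2.0, 1.5]


def test_pseudo_nn_requires_large_enough_subsets():
    prox = np.array([0.9, 0.8, 0.7])
    with pytest.raises(DataError, match="subset"):
        clinical_pseudo_nn(prox, np.array([True, True, False]), k=2)


# --- a frozen 6-train / 2-test instance (K = 2), from the loop oracle --------

CLIN6 = np.array([
    [0.90, 0.10, 0.80, 0.30, 0.30, 0.05],
    [0.20, 0.75, 0.10, 0.75, 0.60, 0.40],
])
MOL6 = np.array([
    [1.00, 0.30, 0.70, 0.10, 0.25, 0.05],
    [0.30, 1.00, 0.20, 0.60, 0.50, 0.35],
    [0.70, 0.20, 1.00, 0.15, 0.40, 0.10],
    [0.10, 0.60, 0.15, 1.00, 0.45, 0.55],
    [0.25, 0.50, 0.40, 0.45, 1.00, 0.65],
    [0.05, 0.35, 0.10, 0.55, 0.65, 1.00],
])
C_OK6 = np.array([True, False, True, False, True, False])
M_OK6 = np.array([True, True, False, False, True, True])


def test_frozen_six_train_instance():
    res = reclassification_scores(CLIN6, MOL6, C_OK6, M_OK6, k=2)
    assert np.allclose(res.right, [2.0, 18.5])
    assert np.allclose(res.wrong, [6.25, 2.5])
    assert np.allclose(res.rs, [-4.25, 16.0])
    assert list(res.ranking) == [1, 0]


def test_g_sign_semantics():
    """Correct molecular neighbors packed at the closest ranks and wrong ones
    maximally distant give a positive G (a 'safe' region)."""
    n = 8
    prox = np.full((n, n), 0.0)
    np.fill_diagonal(prox, 1.0)
    # sample 0: correct neighbors 1,2 very close, wrong neighbors 6,7 far
    prox[0, 1] = prox[1, 0] = 0.9
    prox[0, 2] = prox[2, 0] = 0.8
    prox[0, 6] = prox[6, 0] = 0.01
    prox[0, 7] = prox[7, 0] = 0.005
    m_ok = np.array([True, True, True, True, True, True, False, False])
    g = g_scores(prox, m_ok, k=2)
    assert g[0] > 0


def test_rs_equals_clinical_contrast_when_g_is_constant():
    """With every G equal, RS reduces to the clinical rank contrast: the
    regime in which the two G factors carry no information and the weighted
    clinical ranks dominate."""
    rng = np.random.default_rng(1)
    clin = rng.random((3, 8))
    c_ok = np.array([True, False] * 4)
    g0 = 7.0
    for i in range(3):
        ctx = clinical_pseudo_nn(clin[i], c_ok, k=3)
        right, wrong, rs = aggregate_rs(ctx, np.full(8, g0))
        assert rs == pytest.approx(g0 * (ctx.c_r.sum() - ctx.c_w.sum()))


def test_swapping_clinical_flags_negates_rs():
    """Exchanging the clinical correct/wrong labels swaps the Right and Wrong
    sums, so RS changes sign (molecular flags untouched)."""
    rng = np.random.default_rng(3)
    clin = rng.random((4, 10))
    mol = rng.random((10, 10))
    mol = (mol + mol.T) / 2
    np.fill_diagonal(mol, 1.0)
    c_ok = np.array([True] * 5 + [False] * 5)
    m_ok = np.array([True, False] * 5)
    a = reclassification_scores(clin, mol, c_ok, m_ok, k=3)
    b = reclassification_scores(clin, mol, ~c_ok, m_ok, k=3)
    assert np.allclose(b.rs, -a.rs)
    # swapping the flags in BOTH spaces also negates every G, which cancels:
    c = reclassification_scores(clin, mol, ~c_ok, ~m_ok, k=3)
    assert np.allclose(c.rs, a.rs)


def test_positive_scaling_of_g_preserves_the_ranking():
    rng = np.random.default_rng(4)
    clin = rng.random((5, 8))
    c_ok = np.array([True, False] * 4)
    g = rng.normal(size=8)
    base = []
    scaled = []
    for i in range(5):
        ctx = clinical_pseudo_nn(clin[i], c_ok, k=2)
        base.append(aggregate_rs(ctx, g)[2])
        scaled.append(aggregate_rs(ctx, 3.5 * g)[2])
    assert np.allclose(scaled, np.multiply(base, 3.5))
    assert list(np.argsort(base)) == list(np.argsort(scaled))


def test_duplicate_test_rows_get_identical_rs_and_single_sample_ranking():
    res = reclassification_scores(np.vstack([CLIN6[0], CLIN6[0]]), MOL6,
                                  C_OK6, M_OK6, k=2)
    assert res.rs[0] == res.rs[1]
    assert list(res.ranking) == [0, 1]  # tie broken by ascending test index
    single = reclassification_scores(CLIN6[:1], MOL6, C_OK6, M_OK6, k=2)
    assert list(single.ranking) == [0]


def test_brute_force_agreement_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        clin, mol, c_ok, m_ok, k = random_rs_instance(rng)
        for variant in ("difference", "split"):
            res = reclassification_scores(clin, mol, c_ok, m_ok, k,
                                          g_variant=variant)
            r, w, s = brute_rs(clin, mol, c_ok, m_ok, k, g_variant=variant)
            assert np.allclose(res.right, r, atol=1e-9)
            assert np.allclose(res.wrong, w, atol=1e-9)
            assert np.allclose(res.rs, s, atol=1e-9)


def test_blind_mapping_is_seeded_and_distinct():
    a = reclassification_scores(CLIN6, MOL6, C_OK6, M_OK6, k=2,
                                blind_rng=np.random.default_rng(5))
    b = reclassification_scores(CLIN6, MOL6, C_OK6, M_OK6, k=2,
                                blind_rng=np.random.default_rng(5))
    assert np.array_equal(a.rs, b.rs)


def test_negate_switch_flips_scores_and_ranking():
    a = reclassification_scores(CLIN6, MOL6, C_OK6, M_OK6, k=2)
    b = reclassification_scores(CLIN6, MOL6, C_OK6, M_OK6, k=2, negate=True)
    assert np.allclose(b.rs, -a.rs)
    assert list(b.ranking) == list(a.ranking)[::-1]


def test_rs_result_table():
    res = reclassification_scores(CLIN6, MOL6, C_OK6, M_OK6, k=2,
                                  sample_ids=["t1", "t2"])
    frame = res.to_frame()
    assert list(frame.index) == ["t1", "t2"]
    assert list(frame.loc["t2", ["right", "wrong", "rs"]]) == [18.5, 2.5, 16.0]
    assert frame.loc["t2", "rank"] == 1
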