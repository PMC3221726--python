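"""The re-classification score (RS): rank-based pseudo nearest neighbors in
the clinical space, the indirect Neighbor's-Neighbors mapping into the
molecular space, and their aggregation.

For a test sample i, only clinical features are available.  Its local error
structure in the clinical space is summarized by weighted closeness ranks of
its K nearest *correctly* and K nearest *wrongly* classified training
neighbors,

    C_ij^R = R_ij^R / j,      C_ij^W = R_ij^W / j,        j = 1..K,

where R_ij^R (R_ij^W) is the closeness rank, among all training samples, of
the j-th closest correctly (wrongly) classified neighbor.  Small C^W and
large C^R mean wrong neighbors crowd the test sample: a bad neighborhood.

Each clinical neighbor l is a training sample, so its molecular position is
known even though the test sample's is not.  Its molecular neighborhood
quality is

    G_l^R = sum_t R~_lt^R / t,   G_l^W = sum_t R~_lt^W / t,   G_l = G_l^W - G_l^R,

with R~ the closeness rank (among all training samples, sample l itself
included at rank 1 in its own correct-or-wrong list) of l's t-th nearest
correctly / wrongly classified molecular neighbor.  Positive G_l marks a
molecularly "safe" region: correctly classified samples sit closer to l
than wrongly classified ones.  Aggregating over the clinical neighborhood,

    Right_i = sum_j C_ij^R * G_{CR(ij)},   Wrong_i = sum_j C_ij^W * G_{CW(ij)},
    RS_i    = Right_i - Wrong_i,

and test samples are ranked by RS in descending order: the top-ranked
fraction is passed to the molecular classifier.  Because every ingredient is
a rank, RS is invariant to any strictly increasing transform of the
proximities within a space.

When a subset demanded by the K=1 fallback is empty (e.g. no wrongly
classified sample exists in a space), the corresponding term contributes 0.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import TrainingState
from .io import DataError
from .proximity import ProximityModel, ProximityView, closeness_ranks, \
    proximity_to_training, train_proximity_matrix


@dataclasses.dataclass
class NeighborContext:
    """Clinical-space pseudo-NN information for one test sample.

    ``cr_idx``/``cw_idx`` are the training indices of the K nearest correctly
    / wrongly classified clinical neighbors (j = 1..K); ``rank_r``/``rank_w``
    their closeness ranks among all training samples; ``c_r``/``c_w`` the
    weighted ranks C_ij = R_ij / j.  Arrays may be shorter than K only when
    the corresponding subset is smaller than K (K = 1 fallback).
    """

    cr_idx: np.ndarray
    cw_idx: np.ndarray
    rank_r: np.ndarray
    rank_w: np.ndarray
    c_r: np.ndarray
    c_w: np.ndarray


@dataclasses.dataclass
class RSResult:
    """Per-test-sample Right, Wrong and RS, with the descending ranking."""

    right: np.ndarray
    wrong: np.ndarray
    rs: np.ndarray
    ranking: np.ndarray  # test indices, RS descending, ties by ascending index
    sample_ids: Sequence | None = None

    def to_frame(self) -> pd.DataFrame:
        rank = np.empty(len(self.rs), dtype=int)
        rank[self.ranking] = np.arange(1, len(self.rs) + 1)
        frame = pd.DataFrame({
            "right": self.right, "wrong": self.wrong, "rs": self.rs, "rank": rank,
        })
        if self.sample_ids is not None:
            frame.index = pd.Index(self.sample_ids, name="sample")
        return frame

    def top(self, k: int) -> np.ndarray:
        """Indices of the k top-RS samples (deterministic under ties)."""
        return self.ranking[:k]


def _take_nearest(ranks: np.ndarray, subset: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest members of ``subset``, by closeness rank."""
    if subset.size == 0:
        return subset
    order = subset[np.argsort(ranks[subset], kind="stable")]
    return order[:min(k, subset.size)]


def clinical_pseudo_nn(prox_row: np.ndarray, clinical_correct: np.ndarray,
                       k: int) -> NeighborContext:
    """Pseudo nearest-neighbor scores of one test sample in the clinical space.

    ``prox_row`` holds the test sample's proximities to all training samples;
    ``clinical_correct`` flags which training samples the clinical classifier
    got right (out of fold).
    """
    prox_row = np.asarray(prox_row, dtype=float)
    clinical_correct = np.asarray(clinical_correct, dtype=bool)
    if prox_row.shape[0] != clinical_correct.shape[0]:
        raise DataError("proximity row and flag vector length mismatch")
    ranks = closeness_ranks(prox_row)
    correct = np.flatnonzero(clinical_correct)
    wrong = np.flatnonzero(~clinical_correct)
    if (correct.size < k or wrong.size < k) and k > 1:
        raise DataError(f"K={k} exceeds a clinical subset size "
                        f"({correct.size} correct, {wrong.size} wrong)")
    cr = _take_nearest(ranks, correct, k)
    cw = _take_nearest(ranks, wrong, k)
    j_r = np.arange(1, cr.size + 1)
    j_w = np.arange(1, cw.size + 1)
    return NeighborContext(
        cr_idx=cr, cw_idx=cw,
        rank_r=ranks[cr], rank_w=ranks[cw],
        c_r=ranks[cr] / j_r, c_w=ranks[cw] / j_w,
    )


def g_score_components(mol_prox: np.ndarray, molecular_correct: np.ndarray,
                       k: int) -> tuple[np.ndarray, np.ndarray]:
    """Molecular-space weighted rank sums (G_l^R, G_l^W) per training sample.

    ``mol_prox`` is the training-set self-proximity matrix in the molecular
    space.  Sample l is included in its own subset (correct list if the
    molecular classifier got it right, else the wrong list) at rank 1; the
    opposite list starts at its nearest genuine neighbor.
    """
    mol_prox = np.asarray(mol_prox, dtype=float)
    molecular_correct = np.asarray(molecular_correct, dtype=bool)
    n = molecular_correct.shape[0]
    if mol_prox.shape != (n, n):
        raise DataError("molecular proximity matrix shape mismatch")
    correct = np.flatnonzero(molecular_correct)
    wrong = np.flatnonzero(~molecular_correct)
    if (correct.size < k or wrong.size < k) and k > 1:
        raise DataError(f"K={k} exceeds a molecular subset size "
                        f"({correct.size} correct, {wrong.size} wrong)")
    weights = 1.0 / np.arange(1, k + 1)
    g_r = np.empty(n)
    g_w = np.empty(n)
    for l in range(n):
        ranks = closeness_ranks(mol_prox[l], first=l)
        near_r = _take_nearest(ranks, correct, k)
        near_w = _take_nearest(ranks, wrong, k)
        g_r[l] = float(ranks[near_r] @ weights[:near_r.size])
        g_w[l] = float(ranks[near_w] @ weights[:near_w.size])
    return g_r, g_w


def g_scores(mol_prox: np.ndarray, molecular_correct: np.ndarray,
             k: int) -> np.ndarray:
    """The combined molecular neighborhood score G_l = G_l^W - G_l^R.

    Positive G_l: wrongly classified molecular neighbors sit farther from l
    than correctly classified ones (a "safe" molecular region).
    """
    g_r, g_w = g_score_components(mol_prox, molecular_correct, k)
    return g_w - g_r


def aggregate_rs(ctx: NeighborContext, g_right: np.ndarray,
                 g_wrong: np.ndarray | None = None) -> tuple[float, float, float]:
    """Combine the clinical pseudo-NN scores with the mapped G scores.

    ``Right`` couples the correctly classified clinical neighbors with
    ``g_right`` evaluated at them, ``Wrong`` the wrongly classified neighbors
    with ``g_wrong`` (defaults to ``g_right``, i.e. a single shared G
    vector).
    """
    if g_wrong is None:
        g_wrong = g_right
    right = float(ctx.c_r @ g_right[ctx.cr_idx]) if ctx.cr_idx.size else 0.0
    wrong = float(ctx.c_w @ g_wrong[ctx.cw_idx]) if ctx.cw_idx.size else 0.0
    return right, wrong, right - wrong


def reclassification_scores(
    clin_prox: np.ndarray,
    mol_prox: np.ndarray,
    clinical_correct: np.ndarray,
    molecular_correct: np.ndarray,
    k: int,
    *,
    blind_rng: np.random.Generator | None = None,
    negate: bool = False,
    g_variant: str = "difference",
    sample_ids: Sequence | None = None,
) -> RSResult:
    """RS for a test set, from proximity matrices and correctness flags.

    ``clin_prox`` is (n_test, n_train): clinical proximities of the test
    samples to the training set.  ``mol_prox`` is the (n_train, n_train)
    molecular self-proximity matrix.  ``blind_rng``, when given, permutes the
    G scores across training samples ("blind" mapping; used to quantify what
    the indirect mapping contributes).  ``negate`` flips the sign convention
    for users whose downstream tooling re-classifies from the bottom of the
    ranking.

    ``g_variant`` selects the reading of the aggregation step:
    ``"difference"`` (default) uses the single combined score
    G_l = G_l^W - G_l^R for both terms; ``"split"`` couples Right with
    G^R and Wrong with G^W, the reading under which the two G factors are
    roughly equal in uninformative molecular neighborhoods so that the
    clinical C terms dominate the RS.
    """
    clin_prox = np.atleast_2d(np.asarray(clin_prox, dtype=float))
    if g_variant not in ("difference", "split"):
        raise ValueError("g_variant must be 'difference' or 'split'")
    g_r, g_w = g_score_components(mol_prox, molecular_correct, k)
    if g_variant == "difference":
        g_right = g_wrong = g_w - g_r
    else:
        g_right, g_wrong = g_r, g_w
    if blind_rng is not None:
        perm = blind_rng.permutation(len(g_right))
        g_right, g_wrong = g_right[perm], g_wrong[perm]
    m = clin_prox.shape[0]
    right = np.empty(m)
    wrong = np.empty(m)
    for i in range(m):
        ctx = clinical_pseudo_nn(clin_prox[i], clinical_correct, k)
        right[i], wrong[i], _ = aggregate_rs(ctx, g_right, g_wrong)
    rs = right - wrong
    if negate:
        rs = -rs
    ranking = np.lexsort((np.arange(m), -rs))
    return RSResult(right=right, wrong=wrong, rs=rs, ranking=ranking,
                    sample_ids=sample_ids)


def rs_for_test_set(
    state: TrainingState,
    clinical_model: ProximityModel,
    molecular_model: ProximityModel,
    X_clin_test: np.ndarray,
    *,
    blind_rng: np.random.Generator | None = None,
    negate: bool = False,
    g_variant: str = "difference",
    sample_ids: Sequence | None = None,
) -> RSResult:
    """RS for a test set given fitted proximity forests and a training state.

    Only the test samples' *clinical* features enter: the molecular side is
    reached indirectly through the training samples' recorded leaves.
    """
    view: ProximityView = proximity_to_training(clinical_model, X_clin_test)
    mol_prox = train_proximity_matrix(molecular_model)
    return reclassification_scores(
        view.values, mol_prox,
        state.clinical_correct, state.molecular_correct, state.k,
        blind_rng=blind_rng, negate=negate, g_variant=g_variant,
        sample_ids=sample_ids,
    )
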