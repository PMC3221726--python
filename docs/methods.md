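# Methods

## The two-stage (stepwise) classifier

`stepclf` implements a cost-efficient binary classifier for settings where
every sample has cheap clinical covariates but molecular profiling (e.g.
gene expression) is expensive and should be bought only where it pays.  The
procedure:

1. Classify every training sample in each space separately and record, per
   sample, whether the clinical and the molecular classifier got it right.
   These correct/wrong flags are **out-of-fold** predictions (default
   10-fold, hyperparameters tuned by inner CV): resubstitution flags from a
   forest are near-perfect and would degenerate the downstream counts.
2. Fit one random forest per space on the true labels and use shared
   terminal nodes as the similarity: `S(a, b)` = fraction of trees in which
   `a` and `b` land in the same leaf.  Only closeness *ranks* (1 = most
   proximal, ties broken by ascending training index) are used afterwards,
   because the raw proximity distributions differ radically between a
   low-dimensional clinical space (many exact zeros) and a high-dimensional
   molecular space (almost none).
3. For a new sample, only its clinical features are available.  Its local
   error structure is summarized by the weighted ranks of its K nearest
   correctly and wrongly classified clinical neighbors,
   `C_ij^R = R_ij^R / j` and `C_ij^W = R_ij^W / j`, where the rank is taken
   among all training samples and the neighbor is the j-th closest member of
   the correct (wrong) subset.
4. Each clinical neighbor `l` is a training sample, so its molecular
   neighborhood is known ("Neighbor's Neighbors" indirect mapping).  Its
   molecular safety score is `G_l = G_l^W − G_l^R` with
   `G_l^X = Σ_t R~_lt^X / t` over its K nearest correctly/wrongly classified
   molecular neighbors; `l` itself joins its own subset at rank 1.
5. The re-classification score is
   `RS_i = Σ_j C_ij^R G_{CR(ij)} − Σ_j C_ij^W G_{CW(ij)}`.
   Test samples are ranked by RS in descending order and the top fraction
   `p` is re-classified with the molecular classifier; the rest keep their
   clinical label.

K is global and self-tuning: `K = min(NCW, NCR, NGW, NGR)` over the four
correct/wrong counts, with `K = 1` when a perfect classification would give
0.  When the `K = 1` fallback leaves a required subset empty (no wrongly
classified sample in a space at all), that term contributes 0.

### Conventions the defining equations leave open

* **Rank reference set.**  Ranks in the C and G scores are closeness ranks
  among *all* training samples, while neighbors are selected within the
  correct/wrong subsets.  Ranking within each subset instead would make the
  j-th subset neighbor's rank identically j and reduce every C to 1 — a
  degenerate score — so the global reference set is the only consistent
  reading.
* **Sign and direction.**  The equations are implemented literally and the
  direction was validated behaviorally: on synthetic data with a planted
  clinically-misleading subgroup, the planted test samples receive the
  *higher* RS (enrichment in 20/20 replicates at n = 200), so descending-RS
  re-classification targets exactly the samples molecular data can rescue.
  A `negate=True` switch accommodates tooling with the opposite convention.
* **G aggregation variant.**  `g_variant="difference"` (default) couples
  both Right and Wrong with the single score `G_l = G_l^W − G_l^R`;
  `g_variant="split"` couples Right with `G^R` and Wrong with `G^W`.  In our
  simulations the default reproduces the expected indirect-mapping behavior
  (see below) and is kept.
* **Self-inclusion.**  In the molecular space a training sample joins only
  its own subset (correct list if molecularly correct, else wrong list) at
  rank 1; the other list starts at its nearest genuine neighbor.

## Proximity bandwidth

Proximity forests are classification forests fit on the true labels with
`min_samples_leaf = 5` (default; `T = 500` trees, Monte-Carlo error of the
proximity ~ 1/sqrt(T)).  The minimum leaf size acts as the bandwidth of the
similarity.  Fully grown trees isolate isolated wrong-labelled training
points into singleton leaves; a test sample sitting right next to such a
point then shares leaves with the surrounding bulk instead of with it, and
the local-error signal the RS needs is erased.  With leaves of a few
samples, a leaf is a small mixed neighborhood and the wrong-neighbor
structure survives.  We verified this directly: with fully grown trees the
10-NN wrong-neighbor fraction around planted misleading samples is at the
background rate, while `min_samples_leaf = 5` restores the enrichment.

## Evaluation protocol

`evaluate_curve` runs repeated stratified k-fold CV (default 10x10, as is
conventional for these sample sizes).  Within each fold: the correct/wrong
flags come from inner out-of-fold predictions on the training part only
(test labels never reach the RS), both proximity forests are refit, the
final classifiers are tuned and fit on the training part, and the fold's
test samples are re-classified at each grid proportion
(`ceil(p * m)` samples, nested across p).  By construction the curve at
p = 0 (p = 1) equals the clinical-only (molecular-only) CV accuracy on the
same folds — an identity the tests assert exactly, per fold.  Plain and
class-balanced accuracy are both reported; the spread is across repeats
(across folds when there is a single repeat).  The second stage uses
molecular data only; `second_stage="both"` exposes the variant that
additionally feeds the clinical design to the second-stage classifier; it
is off by default because a high RS means precisely that the clinical view
of that sample is unreliable, so mixing it back in at the second stage is
expected to do more harm than good.

Prospectively, a chosen proportion is converted into an RS cut point (the
matching empirical quantile of the study RS values); new samples are scored
one at a time from clinical data alone and deferred to molecular
measurement when their RS reaches the cut point.  Deferral counts can be
monitored against the intended proportion (binomial bands).

## Synthetic study conditions

The generator emulates paired clinical/expression cohorts (e.g. a breast
cancer series with ~5500 genes and 8 mixed-type clinical variables, or a
CNS tumor series with 60 patients and 7128 genes):

* n = 120 samples by default (n = 200 for the enrichment study below),
  balanced classes; 5 continuous, 2 binary, 1 nominal (3 levels), 1 ordinal
  (4 levels) clinical variables; p = 300 molecular features of which 30
  carry signal.  These sizes keep repeated CV affordable while preserving
  the low-dimensional-vs-high-dimensional contrast that drives the method.
* Class signal: mean shifts of `clinical_effect` / `molecular_effect` SD
  units; categorical variables are thresholded latent normals carrying the
  same shift, so they are informative without a separate mechanism.
* Cross-space correlation: clinical continuous feature j and the molecular
  signal features that share its latent factor both load on it with
  `sqrt(rho)`, giving within-class correlation rho.
* Planted subgroups ("bad neighborhoods"): a fraction of one class whose
  features in the misleading space are drawn from the opposite class's
  distribution, displaced by a fixed cluster offset (norm
  `subgroup_shift = 1.5`) orthogonal to the class axis.  The offset is what
  makes the subgroup a coherent *cluster* on the wrong side of the decision
  border rather than samples indistinguishable from the clean opposite
  class — without it no clinical-space score could single them out, and the
  classifier errors it causes could not be localized.  Planting in a single
  class keeps the two class regions' local error rates asymmetric, which is
  what the RS detects.

Scenario presets (rho = 0.3): **A** molecular better (clinical effect 1.4
with a 20% clinically misleading subgroup in class 1; molecular effect 1.0),
**B** equal (1.1 vs 1.0, no subgroups), **C** clinical better (1.8 vs 0.5
with a 20% molecularly misleading subgroup).  Effect sizes were calibrated
once against the presets' defining contract — the ordering and closeness of
the two endpoint CV accuracies — and then frozen.

The indirect-mapping property is tested on preset A augmented with a
both-spaces-misleading subgroup (15% of class 1) and a molecularly
misleading subgroup (15% of class 0), so that molecular neighborhood quality
actually varies and the mapping has something to transport across spaces;
the "blind" control permutes the G scores across training samples (averaged
over 5 permutations).  With rho = 0.3 the true mapping re-classifies at
least as accurately as the blind control on average; at rho = 0 the two are
statistically indistinguishable.

What the generator does **not** emulate: real covariance among genes
(features are conditionally independent given class and latents), batch
effects, missing clinical values (available in the I/O layer but not
generated), non-Gaussian expression distributions, and survival-type
endpoints.  Passing tests therefore show the machinery behaves as designed
under controlled conditions, not that any particular clinical cohort will
show the same gains.

## Numerical choices and degenerate inputs

* All ties (proximity ranks, RS ranking) break by ascending index; every
  stochastic step takes an explicit seed, so results are bit-reproducible.
* Missing clinical values: median (continuous/ordinal ranks) or most
  frequent level (binary/nominal), fitted on training rows only; category
  codebooks are also fit on training rows, unseen levels fall back to the
  imputation level.  Out-of-fold prediction refits the encoder per fold, so
  a held-out sample never influences other held-out predictions.
* Stratified folds are reduced to the smallest class count when necessary;
  a class with fewer than 2 samples is an error.
* PLS components are clipped to `min(n − 1, p)` with a warning.
* Problem sizes in the test-suite simulations (n = 120–200, p = 300, 3–5
  folds, 100–200 trees, 20 seeds per property) were chosen as the smallest
  sizes at which the scenario contrasts are stable.

## Known limitations

* The RS is a ranking device, not a calibrated probability; its scale
  varies with n and K and should not be compared across studies.
* With very small cohorts the min-count rule can produce K of only 1–3,
  making the RS noisy; the method accepts this by design in exchange for
  having no tunable parameter.
* The indirect mapping contributes little when the clinical-molecular
  correlation is weak (it is then provably equivalent to a blind mapping),
  and is redundant when the correlation is very strong.
* Only binary outcomes are supported, matching the scope of the method.
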