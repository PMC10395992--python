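# Methods

## The dual-task cost model

A motor feature `f_i(Ex, CL_k, s_j)` is measured for subject *j* during
exercise *Ex* ∈ {FTAP, TTHP, GAIT} under cognitive load *k* ∈ {0, 1, 2, 3}
(no task; counting backwards by ones, threes, sevens). The classical
dual-task cost is the percent change against the single-task baseline,

    DTC = (f(CL_k) − f(CL_0)) / f(CL_0) × 100 ,        k ≥ 1.

Its blind spot is the cognitive half of the dual task: a subject who
disengages from counting keeps their motor output unchanged and scores a
reassuring DTC ≈ 0 %. The correct-response count Nc(Ex, CL_k, s_j) is used
as a joint proxy for cognitive efficiency and task commitment. It is
rescaled across subjects, separately within each (exercise, load)
condition, by the bounded affine map

    Zc = (b − a)·(Nc − min Nc) / (max Nc − min Nc) + a ,

with a = 0.01 and b = 1, so the best counter in a condition passes
through unweighted and the worst is shrunk a hundredfold (a stays above
zero to avoid degenerate products). The weighted cost replaces the
dual-task value by f·Zc while keeping the *unweighted* baseline (no
cognitive task exists at CL_0, so no weight is defined there):

    DTC* = (f·Zc − f(CL_0)) / f(CL_0) × 100 .

A disengaged subject's DTC* collapses towards −100 % instead of 0 %.
Despite the historical "Z-scored Nc" name, Zc is a bounded min-max
rescaling, not a standardization; the implementation follows the printed
map literally.

**Orientation before weighting.** The collapse-to-−100 % semantics only
read as "worse" for features where higher raw values mean better
functioning (tapping frequency, gait speed). For a feature with the
opposite polarity (stride-time variability), shrinking the value would
read as an *improvement*, and a later sign flip at the index-construction
stage would turn the commitment penalty into a bonus; with mixed-polarity
feature sets the two halves cancel in the pooled average (we measured
exactly this: inverted index ordering and degraded recovery on synthetic
cohorts). The costs must therefore enter the pipeline uniformly oriented.
`compute_dtc_star` recodes each higher-is-worse feature as its reciprocal
1/f before Eqs. above — a positive-valued, strictly monotone recoding
that preserves percent-change semantics (stride time becomes a
cadence-like rate). Non-positive cells of such features are flagged and
excluded, as are cells with an exactly zero baseline; neither ever
becomes a silent infinity. The sign-flip machinery in the scoring stage
remains available for externally supplied candidate matrices that were
not produced by this recoding path.

Numerical details: the per-condition minimum and maximum counts are
snapped to exactly a and b after the affine map (floating-point addition
can otherwise leave the top weight one ulp short of 1); when all counts
in a condition are equal the weights are set to b = 1, treating uniform
performance as full commitment so that DTC* degenerates gracefully to
DTC.

## Pooled-index construction

Candidate variables are the DTC* values. By default each (feature, load)
pair is a distinct candidate (`per_load` mode: 24 candidates per tapping
exercise, 48 for GAIT, 96 for the TOTAL pool), preserving load-specific
signal; a `load_averaged` switch collapses the three loads per feature
first. Five indices are built: one per exercise, TAPPING over FTAP ∪
TTHP, and TOTAL over all three.

Selection iterates to at most `max_components` (default 6) mutually
weakly correlated components:

1. stop when the set is small enough and every pairwise Spearman |ρ| is
   below the threshold (default 0.4);
2. otherwise delete the single candidate with the largest number of
   above-threshold correlations to others;
3. on a tie, delete the tied candidate with the weakest class
   separation, defined as the maximum pairwise Cohen's |d| over the
   CNA/SCI/MCI pairs (the source procedure names "the weakest ability to
   distinguish among the labels" without a formula; the max over pairs
   is the natural scalarization and requires at least two classes with
   two subjects each);
4. on a further tie — where the original procedure appeals to clinical
   judgement, which is not reproducible — a user-supplied ordered list
   of identities to drop is consulted, falling back to the
   lexicographically smallest identity with a loud warning.

Every deletion is recorded in an audit trail with the criterion used.
Two numerical choices matter here. Deleting a candidate does not change
the pairwise correlations of the remaining ones, so the Spearman matrix
is computed once and subset (a pure optimization, exactly equivalent to
recomputation). And rank correlations are exact rationals that can land
precisely on the 0.4 boundary, where different correlation routines
round to opposite sides; the exceedance test uses |ρ| ≥ threshold − 1e-9,
with the boundary counting as exceeding (the keep condition is strict
|ρ| < 0.4). Constant candidates have undefined correlations; these are
reported and counted as exceeding, so uninformative candidates are
eliminated early. A candidate matrix needs at least three subjects and
two candidates.

Scoring orients each retained component (sign flip where orientation
metadata demands it), min-max normalizes it to [0, 1] on the fitted
sample (z-scoring available), and averages with equal weights. Scores
for subjects outside the fitted range are clipped to [0, 1]. A subject
missing any component value gets a missing index score and is dropped
from downstream models with a logged count, never imputed.

Normalization and selection are fitted on the full sample by default,
matching the single-pass construction of the source procedure; this
leaks the held-out subject's values into the index definition during
cross-validation. A fold-safe mode (`--fold-safe`) refits selection and
normalization inside every training fold. The per-condition rescaling of
Nc inside DTC* remains cohort-wide even then: it is an affine map whose
parameters are two order statistics, and re-deriving it per fold would
change the candidate values themselves; this residual leakage is
documented rather than hidden.

## Group statistics

Continuous covariates are summarized per class as median and IQR
(Q3 − Q1 with linear-interpolation quantiles — the most common default,
stated because quantile conventions differ) and compared with a
tie-corrected Kruskal-Wallis test; the no-variation limit returns
H = 0, p = 1. Pairwise post hocs are two-sided Mann-Whitney tests with
Bonferroni correction (p_adj = min(1, 3p)), using the exact null
distribution when both groups have n ≤ 8 and no ties, the tie-corrected
normal approximation otherwise (clinical group sizes of 10–17 straddle
small-sample territory). Categorical covariates use Pearson χ² without
continuity correction, df = (r−1)(c−1); zero marginal rows or columns
are rejected rather than absorbed. Groups with a single subject make the
tests refuse with a clear error.

## Classification battery

Ten models cross the five indices with two regressor sets, (PI, age) and
(PI, age, FAB), each evaluated on the two-class CNA-vs-MCI problem and
the three-class problem. The three-class model is a single multinomial
(softmax) logit rather than one-vs-rest — the natural reading of a
multivariate logistic model with three outcomes. Fits are maximum
likelihood with a small L2 stabilizer (ridge 1e-6, i.e. C = 1e6) for
separable configurations, via lbfgs with tolerance 1e-8 and a generous
iteration cap (near-separable folds need many iterations before the
tiny ridge caps the coefficient norms); non-convergence raises instead
of warning. Regressors are standardized to the training-fold mean/SD
(constant columns get unit scale), which changes nothing in exact
arithmetic but conditions the optimization.

Validation is leave-one-out: n fits per model, the held-out subject
predicted by argmax class probability, probability ties broken towards
the canonical order CNA < SCI < MCI for determinism, predictions pooled
into one confusion matrix. A training fold that loses an entire class
still yields a prediction from the model restricted to the remaining
classes (the degenerate single-class fold predicts that class) and is
flagged — reachable with only 10 CNA subjects. Two-class metrics treat
MCI as the positive class (sensitivity = MCI recall); three-class
metrics are one-vs-rest recall/precision/F1 per class plus
support-weighted averages, with the precision of a never-predicted class
set to 0. Fractions are kept at full precision and converted to
percentages only at report time.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
for a default cohort of 10 CNA / 17 SCI / 17 MCI subjects:

* **Baseline features**: per-feature normal draws around fixed
  per-feature scales spanning an order of magnitude (so candidates
  genuinely differ in range), floored away from zero.
* **Load degradation**: the fractional worsening at load k is
  `k·load_slope + k·effect_size·sev·noise_sd` plus noise of SD
  `noise_sd`, where sev ∈ {0, 1, 2} indexes CNA/SCI/MCI. `effect_size`
  is therefore the adjacent-class separation in residual-SD units per
  load step; 0 gives an exact exchangeable null for motor features and
  counts. Defaults: load_slope 0.05 (5 % worsening per load step),
  noise_sd 0.05, effect_size 1.0 — chosen to produce battery accuracies
  in the range typical of small clinical MCDT studies (two-class 70–95 %,
  three-class 40–85 %). Half the features are generated higher-is-better
  and half higher-is-worse to exercise the orientation stage.
* **Shared frailty**: a per-subject latent N(0, 1) variable loads (0.5)
  on all of a subject's degradations and (weakly) on their counts,
  inducing the positive inter-feature correlation that makes the
  correlation screen non-trivial.
* **Counts**: truncated-at-zero rounded Gaussians with mean
  `base_k · (1 − class_drop·effect_size·sev − 0.1·frailty)`, base means
  20/12/6 for loads 1/2/3 (counting by sevens yields far fewer responses
  in 15 s than counting by ones) and SD 3. No empirical count
  distributions are published for such protocols; this family was chosen
  for simplicity and controllable separation.
* **Demographics**: ages N(63, 6)/N(72, 9)/N(73, 9) and FAB scores as
  rounded clipped Gaussians (17.8/17.0/15.0 locations, 18-point
  ceiling), reproducing the typical memory-clinic profile of a younger
  control group and FAB ordered CNA > SCI > MCI; sex and education
  follow class-specific categorical draws.

What the generator does **not** emulate: raw inertial time series,
within-session learning or fatigue, non-Gaussian feature tails, missing
data, and any calibration of count distributions to real cohorts.
Passing tests therefore demonstrate the pipeline's correctness and its
behaviour under controlled signal, not clinical performance on real
data.

## Calibration checks and problem sizes

The test suite verifies, besides per-operation oracles (hand-computed
fixtures, exhaustive enumeration for small Mann-Whitney samples, an
independent re-implementation of the selection flowchart, sklearn as a
metric cross-check): with effect_size 2 and the 10/17/17 class sizes,
the pipeline's mean two-class LOOCV accuracy over 20 seeds exceeds 90 %
(measured ≈ 95 %); on fully exchangeable null cohorts (effect 0, equal
age/FAB distributions) the mean stays at or below the upper 95 %
binomial bound of the majority rate 17/27 on the pooled prediction
count. The null mean sits slightly *below* the majority rate
(≈ 56–62 %): leave-one-out removes the held-out subject from the
training prior, which under the null anti-correlates predictions with
truth — a known pessimistic bias of LOOCV with imbalanced classes, so
only the no-spurious-signal direction is bounded tightly. Simulation
sizes (20 seeds, 44-subject cohorts) keep the full suite and the
acceptance script to a few minutes while leaving the binomial bands
narrow enough to be informative.

## Known limitations

* The default (faithful) evaluation builds indices on the full sample;
  reported LOOCV accuracies are optimistic relative to the fold-safe
  mode. Both are exposed.
* DTC* conflates motor degradation with counting performance by
  construction; with strongly class-dependent counts the indices can be
  driven more by Nc than by kinematics. This is a property of the
  statistic, inherited deliberately.
* The criterion-4 tie-break replaces clinical judgement with a
  deterministic priority list; selections that reach it are flagged
  loudly and should be reviewed.
* XLSX import covers the package's own documented layouts; adapters for
  external spreadsheet layouts must map columns to the long schema
  first.
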