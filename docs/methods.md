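# Methods

This note documents the models and procedures implemented in
`empadecode`, their assumptions, the defaults, and the numerical and
design choices a maintainer would want stated.

## The analysis the package implements

The package reproduces, as tested and reusable code, the analysis chain
of a dynamic neuro-decoding study of cognitive empathy (CE: judging the
emotion depicted in a scene) and affective empathy (AE: rating one's own
resonance) in groups with high vs. low autism-like traits (ALT).  The
design: 2 groups x 2 task blocks; 20 grayscale emotional-scene stimuli
(10 positive, 10 negative) shown 16 times each per block (320 trials),
pseudorandomized; 64-channel EEG epoched from -200 to 500 ms around
stimulus onset at 200 Hz (141 samples).

The chain is: preprocessing -> time-resolved multivariate decoding of
emotion category (per subject) -> temporal generalization ->
decoding-based representational similarity analysis (RSA) against two
model RDMs -> cluster-based permutation inference -> single-subject
latency metrics and brain-behavior correlations -> behavioral mixed
ANOVA / Bayes factors / a-priori power.

Because the study's raw EEG is not public, a synthetic-data generator
stands in for the recordings.  It is first-class, tested code: the
package's claims about the inferential machinery are claims about what
the machinery recovers from data whose ground truth is known.

## Synthetic data generator

One subject-block is

    X[trial, channel, t] = noise + category term + feature term + exemplar term

* **Noise** — AR(1) Gaussian per trial and channel, stationary SD
  `noise_sd` (default 1, arbitrary units), coefficient `noise_ar1`
  (default 0.5).  This is a deliberate simplification of 1/f EEG
  background: it supplies the temporal autocorrelation that makes
  cluster-level inference non-trivial, but no oscillatory structure,
  no cross-channel correlation, and no artifacts.
* **Category term** — a fixed unit-norm random spatial pattern (drawn
  from `spatial_pattern_seed`, shared across subjects) times a
  raised-cosine-edged boxcar (default onset 100 ms, duration 300 ms,
  10 ms ramps; the soft edges avoid filter ringing) times
  `+category_amplitude` for positive-category trials and `-` for
  negative.  `category_amplitude / noise_sd` is the multivariate SNR.
* **Feature term** — each stimulus carries a mean luminance and a
  contrast value (drawn uniformly from configurable ranges; the real
  images' values are not published).  The features are z-scored across
  the 20 stimuli and projected onto two further spatial patterns,
  orthogonalized against the category pattern and each other, so that
  the distance between two stimuli's signal patterns equals their
  Euclidean distance in the standardized feature plane.  Category and
  feature information therefore live in separable subspaces by
  construction, which is what makes the RSA attribution test a clean
  dissociation.
* **Exemplar term** (default off) — per-stimulus random patterns drawn
  from the subject's own seed, scaled by `exemplar_amplitude`.  This
  models idiosyncratic stimulus-specific responses and is the
  generator's source of *between-subject* representational
  variability.  Without it every simulated subject has an essentially
  identical RDM time course, which degenerates group-level rank
  statistics (see "RSA inference" below).

Pseudorandomization is implemented as "no immediate stimulus
repetition" (the design names only pseudorandom order).  The behavioral
generator draws per-subject Gaussian intercepts plus cell noise under a
configurable group x emotion effect matrix; defaults encode the observed
qualitative pattern (a positive-emotion advantage in accuracy ~0.07 and
rating ~0.7, no group effects), with accuracy clipped to [0, 1] and
ratings to [1, 9].

What the generator does **not** emulate: volume conduction and channel
covariance, 1/f and oscillatory spectra, artifacts (hence ICA is out of
scope; amplitude rejection stands in), non-stationary signal topography,
and realistic behavioral-neural coupling.  Passing tests therefore
demonstrate that the *analysis machinery* is correct and calibrated on
data satisfying its assumptions — not that real EEG satisfies them.

## Preprocessing

Default chain (in the analysis' stated order): common-average
re-reference -> downsample to 200 Hz -> 0.5-20 Hz band-pass ->
peak-to-peak artifact rejection.  Numerical realizations:

* Band-pass: 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`), i.e. zero-phase — latency metrics downstream must not
  be shifted by filter delay.  Reflection padding is set to the maximum
  (epoch length - 1) because the 0.5 Hz corner's impulse response is
  long relative to a 0.7 s epoch; with short padding, edge transients
  measurably leak into the epoch center.
* Downsampling: polyphase resampling (`resample_poly`) with its built-in
  anti-alias filter and linear-extension padding.
* Rejection: a trial is dropped iff any channel's within-epoch
  peak-to-peak range exceeds the threshold (default 12, calibrated once
  against the default AR(1) noise so that the rejection rate stays below
  1%).  This replaces ICA, which the synthetic data give no occasion
  for; the report object keeps the rate visible.
* Baseline correction is off by default (not part of the stated chain)
  and available as an option.

One consequence worth knowing: zero-phase filtering spreads a sharp
effect symmetrically in time, so a 0.5-20 Hz band-pass smears an
injected boxcar signal measurably *backward* into the baseline.  This is
faithful to filtered real data (the same happens to evoked responses)
but means that decoding onsets estimated after filtering are earlier
than the generative onset; simulation checks that assert onset accuracy
therefore decode unfiltered epochs.

## Time-resolved decoding and temporal generalization

At each sample, a linear SVM (C = 1) on the 64-channel vector separates
positive from negative trials under stratified 8-fold CV repeated 8
times with fresh partitions; performance is the AUC of held-out decision
scores (chance 0.5).  One trial = one sample (no pseudo-trial
averaging); features are standardized with train-fold statistics.
Temporal generalization applies the classifier (and its train-time
standardization) fitted at t_train to the held-out trials at every
t_test within the same CV split, so training trials are never tested at
any time point; the diagonal is the time-resolved decoding up to
nothing (identical splits).

Numerical choice: the SVM is solved in the primal
(`LinearSVC(dual=False, tol=1e-3)`).  The dual coordinate-descent solver
stalls on non-separable (chance-level) data — about 20x slower — while
primal and dual solutions give indistinguishable AUC.

## RSA

The neural RDM at each time point holds, for each of the 190 unordered
stimulus pairs, the cross-validated accuracy of a pairwise classifier
(higher decodability = greater dissimilarity).  The pairwise classifier
is a shrinkage LDA: with ~32 trials against 64 channels the pooled
within-class covariance is singular, so it is shrunk toward a scaled
identity with the Ledoit-Wolf automatic intensity.  Pairwise CV is
4-fold stratified by default (16 trials per stimulus cannot support the
8-fold scheme of the whole-task decoding).  Accuracy is cross-validated,
not training accuracy (which would be ~1 always and uninformative).

Because 190 pairs x 141 time points x folds of separate estimator fits
is infeasible on one CPU, the LDA is vectorized across time points:
batched class means, batched scatter matrices, a batched closed-form
Ledoit-Wolf intensity, and batched linear solves.  Tests verify that at
fixed shrinkage the batched estimator reproduces scikit-learn's
`LinearDiscriminantAnalysis(solver='lsqr')` decisions exactly, and that
the batched automatic intensity matches `ledoit_wolf_shrinkage`.

Model RDMs: *low-level* — Euclidean distance in the (luminance,
contrast) plane, features z-scored across stimuli first (otherwise the
higher-variance feature dominates; a raw mode exists); *category* —
dissimilarity 0.5 within category, 1 between, 0 diagonal.  Model fit
over time is the Spearman correlation of the vectorized lower triangles
(190 values), average ranks for ties.  A constant dissimilarity vector
has no defined rank correlation; such time points carry NaN and are
treated as sub-threshold in cluster inference.

## Cluster-based permutation inference

Point statistic: one-tailed Wilcoxon signed-rank across subjects against
the chance level (0.5 for AUC, 0 for rho).  Exact sign-pattern
enumeration for n <= 12 after discarding zero differences; tie-corrected
normal approximation above.  Cluster formation groups contiguous points
with p < 0.05 (runs in 1D; 4-connectivity in 2D generalization
matrices); the cluster mass is the summed *standardized* point statistic
(z), the maxsum convention.  Cluster p-values use the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_perm), so p is never 0 and never
below 1/(n_perm+1).  Only positive (above-chance) clusters are formed.
Defaults: 1000 permutations, alpha 0.05 at both levels.

Null constructions:

* **Against chance** — per permutation, each subject's whole deviation
  time course (or generalization matrix) is sign-flipped independently.
  Whole-course flips preserve the temporal autocorrelation under the
  null.  The underlying description ("flipping the signs of the trial
  labels" for a group test against AUC = 0.5) is interpreted as this
  standard second-level construction, consistent with the
  subject-level Wilcoxon point statistic.
* **RSA** — per permutation, one shared random stimulus permutation
  (identity excluded) is applied jointly to the model RDM's rows and
  columns and every subject's rho course is recomputed; the neural data
  and their dependence structure are untouched.  Implementation detail:
  subject RDM lower triangles are rank-normalized once, so each
  permutation costs one rank transform of the permuted model vector and
  a matrix product.
* **Single subject** — trial labels are shuffled and the decoding
  rerun; pointwise p-values are pooled permutation ranks, the point
  statistic is AUC - 0.5, and each permutation's maximum cluster mass
  (scored against the same pooled pointwise thresholds) forms the null.
  This is the interpretation chosen for "the same cluster-based
  permutation approach" applied within a participant, where no
  across-subject statistic exists.

### A calibration note on rank statistics in small simulated groups

With n simulated subjects the one-tailed Wilcoxon point statistic
saturates (all deviations positive) at p = 2^-n, so at n = 5 the
pointwise threshold is only just reachable and cluster masses carry no
magnitude information.  If, additionally, all subjects share an
identical representational geometry (no exemplar noise), the RSA shuffle
null becomes degenerate: any permuted model that aligns even weakly with
the common geometry drives *every* subject's rho positive and reproduces
the observed (saturated) mass, making the test arbitrarily conservative.
Real data do not behave this way because subjects differ.  The
simulation studies therefore use n >= 6 subjects and, for RSA, exemplar
noise equal in amplitude to the injected signal.

## Single-subject metrics and brain-behavior relations

From each subject's significant decoding clusters: onset latency (start
of the first cluster), sustainability (total duration, counted as
members x sample period with inclusive endpoints — stated explicitly
because millisecond arithmetic differs by convention), peak latency
(time of maximum AUC *within the union of significant clusters* by
default, matching "metrics extracted from significant clusters"; a
global-argmax flag exists).  Non-decoders (no significant cluster) carry
no metrics.  Group comparisons are pooled-variance independent t-tests
over decoders only (Welch by flag).  Brain-behavior relations are
Spearman correlations between each metric and each behavioral
positive-minus-negative difference score, pooling decodable subjects
from both groups (single pooled regression, as in the study's figures).

## Behavioral statistics

* **Mixed ANOVA** — 2 (emotion, within) x 2 (group, between) split-plot
  decomposition computed explicitly on subject means and difference
  scores with unweighted (Type-III) cell means, so it matches common
  software on unbalanced groups.  Partial eta squared =
  SS_effect / (SS_effect + SS_error).  Two classical identities are
  structural and tested: interaction F = squared pooled t on difference
  scores, and SS_total = between-subject + within-subject parts.
  A constant dependent variable (zero error variance) is an error.
* **Bayes factor** — JZS independent-samples t-test: Cauchy prior
  (scale 0.707, the common software default; the source analysis names
  none) on the standardized effect, marginal likelihood by numeric
  integration of the noncentral-t density; BF01 returned.
* **Power** — noncentral-F power of the within-between interaction with
  the G*Power convention: lambda = f^2 N m / (1 - rho), df = ((g-1)(m-1),
  (N-g)(m-1)).  The repeated-measures correlation is not stated in the
  source analysis; rho = 0.5 (the G*Power default) is assumed and
  exposed — it is required to arrive at N = 34 for f = 0.25 at 80%
  power.  The routine returns the smallest N that is a multiple of the
  group count and reaches the target.
* Post-hoc simple effects use plain Bonferroni (p x m).

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at reduced scale so the whole suite fits in
minutes on one CPU; these sizes are package choices, stated here once:
chance calibration at the full geometry (320 trials, 64 channels, 8x8
CV, 10 seeds); family-wise error calibration on 200 simulated 20-subject
null studies with 200 permutations; parameter recovery with 10 seeds x 6
subjects at 16 channels, 8 repetitions, 4-fold x 2-repeat CV; RSA
attribution with 25 simulations per direction, 8 subjects, 20 stimuli x
4 repetitions, 2-fold pairwise CV at 100 Hz.  The calibration inputs for
the family-wise error check are synthetic AUC-like courses (AR(1)
noise around 0.5) rather than full decodings, since the property under
test is the permutation machinery's error rate given exchangeable null
courses.

## Known limitations

* The generator's noise is spatially white; channel covariance can make
  real shrinkage-LDA behavior differ from the simulated regime.
* Single-subject permutation decoding is expensive (each permutation
  refits the full sliding classifier); in pipelines it defaults to
  fewer permutations (100) than the group tests (1000).
* The mixed ANOVA is limited to 2 x 2 (two-level within factor means no
  sphericity issue, epsilon = 1); no Bayesian ANOVA, no >2-level
  factors.
* Exact reproduction of the study's reported Bayes factors and EEG
  cluster windows would require the unreleased raw data; the package
  reproduces the design-level quantities and the machinery's calibrated
  behavior instead.
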