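# Methods

## Task model and design generator

A run presents 28 words of one language. Each trial is three consecutive
listen–imitate cycles: a 1.5 s auditory stimulus (perception), a 1.5 s
imitation epoch starting exactly when the stimulus ends (production), and a
jitter screen; after the third jitter a 3 s fixation baseline and a fourth
jitter close the trial. Jitter durations are drawn uniformly from
{1, 2, 3, 4, 5} s — the source constraints are a 1–5 s range with a 3 s
mean, and the 5-point uniform grid satisfies both while staying aligned with
the 2 s TR. Trial (word) order is a seeded permutation. The run length is
computed from the generated timeline plus a 16 s tail so the last response
is fully sampled (typically ~340–360 volumes of TR = 2 s; the acquisition
length is deliberately not hard-coded because the nominal volume count and
the trial arithmetic cannot both hold exactly). The default grid is
20×20×20 voxels at 3 mm isotropic — a desk-scale stand-in for a whole-brain
acquisition; everything is configurable per design.

## Latent pattern model

Within a region mask, the pattern for (language L, repetition t, word w) is
a unit-variance mixture of independent standard-normal vector components:

    p[L,t,w] = a·g[w] + s_t·h[L,w] + q_t·e[L,t,w],   a² = ρ_cl,
    s_i·s_j = ρ_rep(i,j) − ρ_cl,   q_t² = 1 − ρ_cl − s_t².

So the expected Pearson correlation between a word's Chinese and Spanish
patterns is exactly ρ_cl (`rho_cross_language`), and between the same word's
patterns at repetitions i and j exactly ρ_rep(i,j) (`rho_repetition`; a
scalar or a per-pair dict, constrained to ρ_rep ≥ ρ_cl because language-shared
variance is necessarily repetition-shared in this mixture). The
language-shared component g[w] itself mixes a word-nonspecific regional
response m (weight √η, `word_common_frac`, default 0.5) with a word-specific
vector: all stimuli engage the same speech network, so different-word
cross-language pairs correlate at ρ_cl·η. This matters because the
cross-language searchlight statistic averages *all* 84×84 trial pairs, of
which only 252 are same-word; without a common component the planted effect
would be diluted 28-fold and undetectable at realistic sample sizes.
Outside all masks, patterns are independent noise. Perception and production
use separate latents, optionally correlated at `rho_phase` (default 0 — the
two phases are analyzed separately downstream and nothing in the analysis
requires cross-phase structure).

Note the distinction: `rho_repetition` is a pattern-level correlation. The
repetition *measure* downstream (Spearman correlation of trial-similarity
matrices) is a monotone function of it, not equal to it; the monotonicity is
what the recovery tests assert.

Group defaults (the study conditions): in the single default
"speech-association" region (a 5³ block at the grid center),
ρ_cl = 0.5/0.5/0.1 and ρ_rep = 0.7/0.55/0.3 for control adults / singers /
children — adults share more cross-language structure than children, and
control adults carry the most repetition-stable geometry, children the
least.

## BOLD synthesis and trial-beta estimation

Each word event contributes its pattern scaled by `amplitude` (default 1)
and modulated by its boxcar convolved with the SPM canonical double-gamma
HRF (peak ≈ 5 s, undershoot ≈ 16 s, no derivatives), evaluated on a
20×-oversampled grid and sampled at volume times. Additive white Gaussian
noise (`noise_sd`, default 1 — pattern sd/noise sd = 1) and a random cosine
drift confined to frequencies below 0.01 Hz complete the series; the drift
exists precisely to exercise the high-pass contract of the estimator.

LSS estimation fits, per word event, an OLS model with columns [target
event; combined other same-phase events; combined other-phase events;
optional motion regressors; discrete-cosine drift set with cutoff 0.01 Hz;
intercept] and keeps the target coefficient per voxel. Perception and
production are modeled as separate regressors because the two phases are
analyzed separately; baseline fixation epochs stay unmodeled (implicit
baseline); no prewhitening is applied (the synthetic noise is white). Rank
deficiency raises an error naming the offending columns.

Two estimation facts shape the tests. First, when per-voxel response
amplitudes are constant across trials within a phase, the true signal lies
in the LSS column span and recovery at zero noise is exact (this is the
configuration used for the exactness check). Second, with genuinely
trial-varying patterns, the lumped nuisance column cannot absorb
trial-to-trial variability of overlapping neighbors, so LSS estimates carry
*crosstalk* error even at zero thermal noise: with this dense timing (mean
3 s jitters) the estimated-vs-true pattern correlation is ≈ 0.68 at zero
noise and ≈ 0.35 at noise sd = 1. This is a property of LSS on fast designs,
not of the implementation (which matches a per-voxel least-squares oracle
exactly), and it motivates the next choice.

### Beta-level cohort simulation

Group-level experiments need hundreds of subject datasets. Running the full
BOLD→LSS chain for each would spend nearly all compute re-demonstrating a
stage that is already verified by its own oracle tests, so cohort-scale
simulations draw trial betas directly as `amplitude·pattern +
beta_noise_sd·noise` (default sd 1, float32), emulating the sampling
distribution of LSS estimates (signal plus approximately white estimation
error). The forward chain remains first-class, tested code; the shortcut is
a runtime design choice, not a modeling claim.

## Searchlight measures

Neighborhoods are count-based: the 125 nearest in-mask voxels by Euclidean
world distance (matching the count convention of searchlight toolboxes),
with exact distance ties broken by lexicographic voxel index so results are
deterministic. A KD-tree shortlist (padded by 256 candidates, far beyond any
equal-distance shell multiplicity at k = 125) followed by an exact stable
re-sort makes construction O(n·k) while remaining identical to a full sort;
masks small enough are sorted exhaustively.

Cross-language similarity: every trial's neighborhood vector is centered and
unit-normalized; the mean over all 84×84 pair correlations reduces to the
dot product of the two row-sum vectors divided by 7056, which is what the
vectorized path computes (and the per-neighborhood function, checked against
a nested-loop oracle). The mean r is Fisher z-transformed with |r| clipped
at 1−1e−12. Note an identity worth stating: this statistic is invariant to
trial relabeling — every pair enters the average — so label permutations
cannot serve as its null; the repetition measure below is the
alignment-sensitive one.

Repetition similarity: per repetition, the 28×28 Pearson matrix of trial
pairs; Spearman rank correlation between the two strict upper triangles
(378 entries; the diagonal is constant 1 and carries no rank information),
then Fisher z. Zero-variance trial patterns contribute r = 0 with a warning
rather than NaN, keeping maps finite. Fisher z is applied to the aggregated
statistic only, never to individual pair correlations.

## Group inference

The voxelwise mixed (split-plot) ANOVA uses per-cell subject means, one
between factor (group) and one within factor, classical sums of squares, no
sphericity correction; it is vectorized over voxels and agrees with
pingouin's `mixed_anova` to ~1e−14 per voxel. Conjunctions are
minimum-statistic: a voxel passes only if both one-sided t maps exceed the
voxel p < .001 threshold. Cluster-extent correction replaces random-field
theory with a max-cluster-size permutation: group labels are permuted, the
null distribution of the largest supra-threshold 26-connected cluster is
built, and observed clusters above its 95th percentile survive — the same
control target, verified by null calibration (measured family-wise rate
≈ 0.02 at nominal 0.05, i.e., slightly conservative, as expected from the
discrete strict-inequality rule). PCA composites standardize the distance
variables, take the first principal component, and fix the sign so larger
scores mean larger mean distance (worse imitation). Brain–behavior partial
correlation residualizes both sides on the covariate (with intercept) and
uses the t transform with n−3 dof; residuals that vanish to rounding are
treated as zero association.

## Classification

The 12 similarity maps per subject are voxelwise averaged into one map
(`assemble_features`; a concatenation mode exists behind a switch for the
alternative reading of "averaged"), mean-centered with training-fold means
inside leave-one-subject-out cross-validation, and classified by a linear
SVM with C = 1 (the toolbox default cost; the source does not report one).
Accuracy is the balanced accuracy of the pooled held-out predictions. Two
honest caveats, both verified: mean-centering is a common translation of
train and test, and linear-SVM decisions are invariant to such translations,
so the fold-vs-full centering convention cannot leak label information (the
implementation still uses training folds only, pinned by a reference test);
and leave-one-out on balanced null data is slightly pessimistic (~0.47 at 20
subjects) because the held-out subject's class is always the training
minority — immaterial to the permutation test, whose null carries the same
bias. Permutation significance shuffles full label vectors, recomputes the
LOSO accuracy n_perm times (default 1000), and reports the add-one-corrected
p = (1 + #{perm ≥ obs})/(n_perm + 1). Weight maps from the all-subject fit
are thresholded at 30% of the maximum absolute weight, signs preserved
(contributions to either contrast direction are meaningful), and surviving
26-connected clusters under 100 voxels are removed.

## Acoustics

Seven Spanish-like words carry /b/ (4 words) and /d/ (3 words) and cover the
vowels /a e i o u/. The generator draws per-subject speaker offsets
(between-speaker sd), per-token deviations (within-speaker sd), and
independent per-rater measurement errors; the native reference is a
noiseless token set from one speaker. Default group means put children's VOT
more negative (more native-like prevoicing) than control adults', with
singers in between, and control adults farthest from the native /o/ (and,
with children, far from /i/): VOT /d/ = −70/−40/−55 ms for
children/controls/singers against a native −80 ms, between-speaker sd 12 ms,
within-speaker sd 8 ms — effect sizes chosen so a 20-per-group design
recovers the ordering with high probability, which is what the full-cohort
analysis assumes. Digit span (a working-memory covariate) is generated per
subject, lower in children.

Rater merging averages measurements and reports inter-rater Pearson r per
measure. Lobanov normalization z-scores F1 and F2 per speaker across all
that speaker's vowel tokens (sample sd, ddof = 1); the native reference is
normalized within its own token distribution. Vowel distance is Euclidean in
the normalized plane to the native per-vowel mean position, averaged across
words containing the vowel; VOT distance is the absolute difference to the
native VOT (raw VOT is also carried, since both variants are analyzed).
Group × order inference delegates to pingouin's mixed ANOVA and
Bonferroni-corrected pairwise tests, with partial η² attached to the
contrasts.

## Problem sizes used in the test suite

Oracle-equivalence checks run on 6³ grids with full 84-trial runs. The
parameter-recovery experiment runs at the analysis's stated conditions —
15 subjects/group, three groups, 20³ grid, 10 replicates. Classifier
recovery uses 15 subjects/group on a 10³ grid over 10 seeds; null
calibrations use 100 replicates (cluster FWE) and 50 replicates × 100
permutations (classifier p uniformity). These sizes were fixed from the
stated conditions and runtime estimates of the simulations themselves.

## Known limitations

The generator emulates the statistical structure the analysis assumes —
event timing, region-confined correlation structure, white noise, slow
drift — but not spatial autocorrelation, physiological noise, motion,
susceptibility dropout, or anatomical variability; passing recovery tests
therefore demonstrates correctness of the estimators under their stated
model, not performance on real acquisitions. Acoustic values are generated
at the measurement level; no audio is synthesized and no formant tracking is
performed. The mixed ANOVA supports one within factor (the analyses used
here are all group × one factor); random-field-theory cluster inference and
anatomical labeling of clusters are deliberately out of scope.
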