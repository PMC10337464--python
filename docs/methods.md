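# Methods

`actistate` classifies weekly patient-reported-outcome (PRO) states from
passively collected activity-tracker features. Two models are compared: a
random forest that treats each patient-week independently, and a hidden
Markov model (HMM) that fuses the forest's weekly posteriors with
empirically estimated week-to-week state transitions via the forward
algorithm. This note records the models, their assumptions, the tunable
parameters, and the design choices made where the design was genuinely
open.

## Ordinal state space

Weekly PRO scores are PROMIS t-scores (population mean 50, SD 10) for
pain interference, fatigue, sleep disturbance, physical function and
social activity, plus the Godin leisure-time exercise index. Scores are
discretized into 8 ordinal states: six width-5 (0.5 SD) bins centred on
the instrument's clinical severity threshold — symptom scores threshold
60 (severe at or above), function scores threshold 40 (severe at or
below), Godin 24 (inactive strictly below) — plus two open catch-all
tails. States are labelled by the left edge of their interval; intervals
are half-open `[label, label+5)`, so for threshold 60 the labels are
40, 45, 50, 55, 60, 65, 70, 75 and a score of exactly 60 lands in the
threshold bin while 59.9 lands below it.

Choices worth knowing about:

* **Window placement.** Labels run `threshold − 20 .. threshold + 15`.
  This reproduces the symptom worked example exactly and is applied
  unchanged to function and exercise instruments (for Godin, whose
  threshold is not a multiple of 5, bins are 4, 9, …, 39), keeping one
  code path.
* **Sparse-bin merging.** Bins with fewer than `min_count` (default 40)
  training observations merge iteratively into their threshold-side
  neighbor (the threshold bin itself merges into its fuller neighbor),
  protecting the clinically meaningful boundary. Merging is fit per
  training partition; the merge log is serialized with the scheme.
* **State-level severity.** A state is "severe" when its label
  binarizes as severe. For symptom and exercise instruments this agrees
  with score-level binarization everywhere; for function instruments the
  threshold bin `[40, 45)` contains scores on both sides of the ≤ 40
  rule, and the state follows its label (severe). A merged bin that
  straddles the threshold has no intrinsic side; the experiment harness
  assigns it to the side holding the majority of its training
  observations (and logs that), while the low-level API requires an
  explicit assignment.

## Preprocessing

Daily tracker features (15 of them; sums for duration/count channels,
min/max for heart rate, over a day running 8 PM to 8 PM and labelled by
the interval's end date) are "unmelted" into one 105-slot vector per
patient-week, feature-major (`f_d1..f_d7`). Adherence rules: a week is
dropped when any feature misses ≥ 3 of its 7 days; a patient is excluded
at ≥ 3 dropped weeks ("more than 2", read strictly); remaining gaps in
retained, non-dropped weeks are imputed with the same patient's
previous-week feature mean.

Where the convention was open:

* Previous-week imputation uses the immediately preceding calendar week
  even if it was dropped (its observed values are still informative); a
  flag restricts it to non-dropped weeks.
* First-week gaps (no previous week) fall back to the patient's own
  mean of that feature over all their observed days, then to the cohort
  mean — keeping every retained week usable. Imputation uses
  patient-specific means; imputation is idempotent and never alters drop
  flags, which are computed on raw missingness.
* Weeks with features but no survey are retained as observation-only
  steps for the forward filter but excluded from supervised training and
  from metric computation, preserving temporal continuity.

## Per-week random forest

The forest classifies the 105-slot vector into the PRO's state:
100 trees, Gini splitting, maximum depth 25, minimum 10 samples to
split; seeded per evaluation round. Posteriors are returned over the
full state space with zero mass on classes absent from training
(floored downstream). Feature importances are slot-level impurity
importances summed (not averaged — the choice is immaterial after
normalization over equal-sized groups) over each feature's 7 day
columns and renormalized, giving the 15-row ranked table. Demographic
covariates are not used: the feature vector is exactly the 15 × 7
tracker slots.

## Forward-filter HMM

The hidden state is the week's PRO state; the observation is the week's
feature vector. Emissions are obtained by Bayes inversion of the
forest's posterior, `P(x|y) ∝ S(y|x) / P(y)`, with the constant `P(x)`
dropped — valid because every belief is renormalized. Posteriors and
priors are floored at 1e-12 and 1e-6 respectively so a class absent from
a training split cannot zero out or blow up a belief. Transition
matrices are estimated by counting consecutive-week state pairs in
training sequences (a dropped or unanswered week breaks the chain),
add-α smoothed (α = 1 by default) and row-normalized; an optional
Gaussian kernel over ordinal state distance can smooth counts toward
neighboring severity states (off by default). The forward recursion
renormalizes per step, which suffices against underflow for 12-week
sequences (verified against an exhaustive path-enumeration oracle to
1e-10). Weeks without usable observations propagate the belief through
the transition matrix with no emission — the standard treatment of
missing observations. Only filtering is implemented: no smoothing,
Viterbi, or Baum–Welch.

## Evaluation design

Each experiment runs `n_repeats` (default 10) rounds. Every round draws
a fresh patient-disjoint 80/20 split (patient-level, to prevent leakage
across one patient's weeks; re-splitting rather than only re-seeding the
forest gives the more conservative SDs), fits bin merges, the forest,
transitions and the prior on the training side only, and evaluates on
held-out patients' week sequences. Metrics: rank-based ROC-AUC for the
binary severe-vs-normal task, scored threshold-free by severe-side
probability mass (belief mass for the HMM, posterior mass for the
forest — identical scoring for a fair comparison); Pearson r and
quadratic-weighted Cohen κ (weights `(i−j)²/(S−1)²` over the full state
space) on ordinal state indices for the multiclass task. Zero-variance
Pearson cases and single-class AUC rounds are recorded as missing with a
warning and excluded from round means rather than coerced to a number.
HMM-vs-forest differences are tested per PRO with a paired two-sided
t-test over round-level values (Wilcoxon available by flag); identical
or degenerate inputs report p = 1. Report tables carry per-PRO means and
SDs; column means and maxima are computed by the same summary code path
used for the published-table arithmetic checks.

## Synthetic cohort generator

No study data are deposited, so the generator produces cohorts with
exactly the statistical structure the analysis assumes:

* **Latent chain.** One weekly severity state per patient, a first-order
  Markov chain with self-transition weight `persistence` (default 0.85)
  and the remainder spread over ordinal neighbors (a lazy reflected
  random walk); initial states from the stationary distribution. An
  alternative `iid` kernel sends the remainder to a uniform draw, so
  `persistence = 0` there yields independent states. The distinction
  matters: under the adjacent kernel, `persistence = 0` forces
  neighbor-only moves, which conserve state parity and are therefore
  *maximally* temporally informative — the right null model for "no
  temporal signal" is the iid kernel, and that is what the
  no-signal property tests use.
* **Features.** Daily values are Gaussian around the published cohort
  means/SDs. Linked features (default: total steps and total activity
  minutes, the two leading importances in practice) shift their mean by
  `effect_size` (default 0.5) SDs per state step. Non-negative channels
  are clipped at zero, with the pre-clip baseline analytically recentred
  (via the closed form for a clipped-Gaussian mean, solved per feature)
  so post-clip marginal means match the published targets exactly; the
  clip slightly compresses the state link at the low extreme of
  high-variance features like steps.
* **Scores.** Each weekly score is drawn uniformly inside the
  generating state's bin (tails truncated to width 5), plus Gaussian
  noise (`score_noise_sd`, default 2 t-score units), clipped to
  [0, 100] — so binning inverts generation exactly at zero noise, a
  clean oracle.
* **Missingness.** Missing-completely-at-random: whole days lose all 15
  features jointly (a tracker left on the charger) with probability 0.10,
  surveys are skipped with probability 0.15; an optional linear
  week-index ramp emulates survey fatigue (off by default). Defaults for
  cohort shape are 250 patients × 12 weeks. Persistence, effect size and
  score noise are free parameters of the emulation — no published
  within-patient correlation pins them down — chosen once as plausible
  for a chronic-disease cohort and documented here.

What passing tests on this cohort do **not** show: real tracker data
have circadian and day-of-week structure, informative (not MCAR)
missingness, heavy-tailed and device-censored feature distributions, and
PRO dynamics that are neither first-order Markov nor uniform-within-bin.
Synthetic results demonstrate correctness of the pipeline and the
qualitative temporal-signal behavior, not clinical performance.

## Problem sizes and numerical choices

Default experiments (250 patients, 10 repeats, one PRO) run in well
under a minute on one core; the exhaustive forward-filter oracle is run
at S ≤ 4 and ≤ 6 weeks where path enumeration is exact and fast.
Transition recovery is checked at 1,000 sequences of length 12 without
smoothing. Ties in argmax predictions break toward the lower state
index, fixed for reproducibility. All randomness flows from explicit
seeds; identical configuration and seed give byte-identical cohort files
and reports.

## Known limitations

The day aggregator handles a single configurable clock boundary, not
timezones or DST. The generator shares one latent chain across all six
PROs of a patient (so their scores are mutually correlated and all carry
signal); per-PRO independent chains would need per-PRO feature links the
emulation does not model. Function-instrument threshold bins mix
score-level severity as described above. Godin scores are generated on
the same 0–100 clipped scale as t-scores for uniformity, though real
Godin indices are unbounded above.
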