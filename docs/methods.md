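# Methods

`actidep` implements an interpretable classification pipeline for wrist-worn
actigraphy in depression research: per-minute activity counts are summarised
into circadian and statistical features, class imbalance is corrected with
adaptive synthetic oversampling, a roster of classifiers is compared under a
repeated cross-validation significance protocol, and predictions are
explained with coalitional Shapley values and LIME local surrogates. This
note records the models, conventions and design choices, and what the
synthetic cohorts do and do not establish about real data.

## Data model and labelling

A cohort joins one per-minute activity recording per participant
(`timestamp,date,activity` CSV) with a demographics/severity table
(`scores.csv`). Group membership (clinical *condition* vs healthy *control*)
is carried by the participant-id prefix, as in the public datasets that use
this dialect. Two targets are supported:

- **binary** — condition = 1, control = 0;
- **severity** — the MADRS score banded as 0–6 normal (0), 7–19 mild (1),
  20–34 moderate (2). Scores of 35+ fall in the severe band, which the
  modelled population does not contain; they raise an error unless
  explicitly mapped to a fourth class. Severity labels default to the
  pre-observation score (`madrs1`); `madrs2` or their mean are config
  options, since either rating could reasonably define severity.

The analysis unit is the **participant-day**: recordings are cut into
consecutive non-overlapping windows of L = 1440 one-minute epochs. Day-level
windows match the sensor cadence and multiply the effective sample size,
which a cohort of tens of participants needs for 10-fold cross-validation.
Timestamp gaps of at most 2 minutes are forward-filled with zeros; a window
spanning a longer gap is dropped and logged. Windows inherit the
participant's label, and **all windows of a participant stay in the same
cross-validation fold** (participant-level stratified splitting) so that
identity never leaks across the train/test boundary.

## Feature set

Thirteen activity features per window plus two demographics (age as the
midpoint of the 5-year age band, gender as the dataset's 1/2 coding):

| family | features | conventions |
|---|---|---|
| time domain | mean, SD, skewness, kurtosis, IQR, lag-1 autocorrelation, histogram entropy | population SD; adjusted Fisher–Pearson skewness; excess kurtosis; IQR by linear-interpolation percentiles; entropy of a 16-bin histogram normalised by log 16 |
| frequency domain | PSD mean, dominant frequency, spectral entropy | Welch averaged modified periodogram: Hann taper, 256-minute segments, 50% overlap, density scaling (sum of ordinates × Δf ≈ sample variance); DC excluded; entropy normalised by log(#bins) |
| circadian | activity onset, activity offset | 60-min centred rolling mean compared against 1.0 × the daily mean; onset/offset are the start of the first and end of the last run of ≥ 30 consecutive supra-threshold minutes |
| transitions | transition entropy | counts discretised into k = 3 states by mid-distribution rank binning (robust to the heavy ties of count data); entropy rate −Σᵢ πᵢ Σⱼ Pᵢⱼ log Pᵢⱼ of the empirical chain, normalised by log k |

Degenerate windows follow explicit conventions: a constant window has SD,
skewness, kurtosis, autocorrelation and entropy all 0; a window with no
sustained activity period (flat day) or an all-zero spectrum has undefined
circadian/spectral features and is **dropped and logged**, never imputed —
mirroring the decision to exclude numerically unstable descriptors rather
than carry undefined values into the models.

With the 256-minute Welch segment the frequency resolution is 1/256
cycles/min, so the circadian fundamental (1/1440) is not resolved as a
separate line; the PSD-mean feature instead captures broadband power, which
is the property the group effects act on. Entropy-type features and the
transition entropy are invariant to rescaling all counts by a positive
constant; mean and SD scale linearly — these invariances are property-tested.

Features are standardised by the z-score z = (x − μ)/σ with μ, σ (population
form) estimated **on training rows only**; constant columns map to zeros
with a warning. `dominant_frequency` is frequently constant across windows
(the broadband peak sits in the first non-DC bin), in which case the scaler
zeroes it — it is retained for datasets with genuinely varying spectral
peaks.

## ADASYN

Adaptive synthetic oversampling is implemented from first principles. For a
minority class m against the pooled rest: the budget G = (m_largest −
m_minority)·β (β = 1 restores full balance); each minority point receives a
share of G proportional to rᵢ, the fraction of its K = 5 nearest neighbours
(searched among all points, Euclidean metric on standardised features) that
belong to other classes; shares are integerised by largest-remainder
rounding (deterministic, monotone, equal weights differ by ≤ 1). A synthetic
point is xᵢ + λ(x_z − xᵢ) with λ ~ U[0,1] and x_z drawn from the K nearest
*minority* neighbours of xᵢ. If no minority point borders the majority (all
rᵢ = 0) the budget falls back to uniform with a warning; a minority class of
one has no synthesis partner and is an error. In more than two classes,
every non-largest class is oversampled one-vs-rest.

Oversampling runs **inside each training fold, after scaler fitting**, so
synthetic points never contaminate evaluation rows. Oversampling before the
split — which inflates apparent performance — is expressible by resampling
the whole matrix explicitly, but is not the default anywhere.

## Models and evaluation

Five families: logistic regression (multinomial by default, one-vs-rest
selectable), RBF support-vector machine (one-vs-rest or one-vs-one),
random forest, gradient-boosted trees (XGBoost), and a two-hidden-layer
(64/32) feed-forward network with early stopping. Hyperparameter defaults
are deliberately conservative (300 trees, depth 6, learning rate 0.1 for
boosting) and fully overridable from the run config.

Metrics come from the confusion matrix: accuracy, precision TP/(TP+FP),
recall TP/(TP+FN), specificity TN/(TN+FP), F1, and the Matthews correlation
coefficient. Multiclass metrics combine per-class one-vs-rest values by
support-weighted averaging (macro available) — under which weighted recall
equals accuracy, an identity the tests assert — while the multiclass MCC is
the generalised k-class correlation on the full matrix, not a per-class
average. Zero-denominator cells yield 0 with a warning.

Model comparison uses 10-fold × 3-repeat stratified cross-validation
(30 paired folds on an identical fold sequence for every model) scored with
F1, followed by paired two-tailed t tests of the boosted baseline against
each rival and Holm step-down correction at family-wise α = 0.05. Degenerate
paired tests are defined explicitly: identical fold scores give p = 1; a
constant nonzero difference has divergent t and is reported as p = 0 with a
warning.

## Explanations

The Shapley value of feature i, φᵢ = Σ_{S⊆N∖{i}} |S|!(|N|−|S|−1)!/|N|! ·
[v(S∪{i}) − v(S)], uses the marginal-replacement value function: v(S) is the
model's score averaged over a background sample with the features in S set
to the explained instance's values. The background defaults to a seeded
subsample of 50 training rows; a single baseline vector is the n = 1 special
case. Exact computation enumerates all 2^p coalitions (feasible to p = 16);
beyond that a permutation-sampling estimator is used, unbiased before a
final additive renormalisation that restores the efficiency identity
Σφᵢ = f(x) − v(∅) exactly (flagged in the output). Efficiency, dummy and
symmetry axioms are asserted against brute-force enumeration in the tests.
Multiclass attributions are computed per class score. Tree-specific fast
algorithms are deliberately out of scope: enumeration plus sampling keeps
the implementation model-agnostic and directly testable against the
definition.

LIME discretises each feature into training-set quartile bins, draws
perturbation samples (bin uniform, value uniform within the bin), represents
them by same-bin-as-instance indicators, weights them by
exp(−d²/w²) with w = 0.75·√p, and fits a ridge surrogate returning signed
threshold rules ("0.74 < autocorr ≤ 0.78") with the weighted R² of the local
fit. Features with degenerate spread are excluded with a warning. Defaults:
5000 samples, top-10 rules, seeded.

Global importance is the mean |φ| over explained instances. Rankings from
different architectures are compared by Spearman rank correlation and top-k
overlap **within each model's own scale** — attribution magnitudes of a tree
ensemble and a neural network can differ by orders of magnitude, so raw
values are never compared across models.

## Synthetic cohorts

The generator produces Depresjon-dialect cohorts with a controllable
circadian structure. Each participant has a raised-cosine daily activity
profile (zero outside the active span — chosen over a plain sinusoid so
onset/offset have an exact construction ground truth) scaled by a
per-participant amplitude, plus stationary AR(1) Gaussian noise truncated at
zero and rounded — non-negative count data without committing to a count
distribution. Defaults model the study population: 23 condition / 32
control participants, 13 days each.

Planted group effects follow the directions reported for real cohorts:

- **amplitude** 300 ± 75 (control) vs 240 ± 65 (condition) counts — blunted
  activity;
- **AR(1)** 0.35 vs 0.50 (± 0.08 between participants) — smoother, more
  rigid minute-to-minute structure;
- **phase** condition onset shifted ±105 min with random sign per
  participant (phase-delay *or* phase-advance, both documented in mood
  disorders), onset jitter ± 25 min in both groups; active span 960 vs
  915 min (± 50);
- **severity sub-structure**: MADRS ~ N(3, 2) truncated to [0, 6] for
  controls and N(16, 7) truncated to [7, 34] for conditions; moderate cases
  (MADRS ≥ 20) get a further ×0.85 amplitude reduction, +30 min phase delay
  and +0.10 AR increment, making the three-class task learnable.

The between-participant spreads are deliberately large relative to the group
shifts so that held-out-participant classification lands in the published
performance regime (binary F1 ≈ 0.85–0.9) rather than at a ceiling; the
bimodal phase shift is the component a linear model cannot exploit, which is
what gives the boosted trees their reproducible advantage. A second
configuration, `amplitude_dominant_config`, removes the phase and span
effects and widens the amplitude/AR gap so a single planted axis (overall
spectral power) dominates — used for attribution-recovery studies where the
ground-truth driver must be unambiguous.

What the synthetic cohorts do **not** emulate: non-stationary day-to-day
habit changes, weekday/weekend structure, medication or comorbidity
covariates, missing-wear artefacts, or the heavy-tailed burstiness of real
accelerometer counts. Passing the recovery studies shows the pipeline's
machinery is correct and sensitive at realistic effect sizes; it does not
certify performance numbers on any real dataset.

## Problem sizes and determinism

Every stochastic stage (generation, fold assignment, ADASYN, model seeds,
Shapley background and permutations, LIME sampling) derives from a single
integer seed; fixed seeds give bit-identical outputs. The replicate studies
run at desk scale as the package's own choice of problem size: model-ordering
and importance-recovery studies use 50 participants/group × 5 days per
replicate (20 replicates in the test suite), the boosted model trimmed to
150 trees there; the ADASYN downstream-recall check uses 12 replicate 1:4
cohorts (10 vs 40 participants × 4 days) scored by pooled participant-level
5-fold CV recall, a scaled-down version of the same property at larger
replicate counts. The onset-recovery test compares the detector against the
analytic threshold-crossing time of the noise-free raised-cosine day (the
crossing sits ~1/5 span after template onset at the default threshold of
1.0 × daily mean), and additionally checks that configured phase shifts
translate the detection one-to-one.

## Known limitations

- Lag-1 autocorrelation of a smooth circadian day is dominated by the trend
  (values ≈ 0.85–0.95); the AR(1) knob moves it monotonically but over a
  compressed range. Longer configurable lags are available where more
  contrast is needed.
- The exact Shapley path is exponential in p by design; p = 15 explanations
  use the permutation estimator, whose rankings carry Monte-Carlo noise that
  shrinks with the permutation budget (40 by default in the studies).
- Shapley credit for a planted effect spreads over correlated feature
  proxies (amplitude moves mean, SD, IQR and PSD mean together); recovery
  checks therefore test top-2 membership of the proxy set, not a unique
  winner.
- LIME's quartile discretisation makes rules coarse when a feature's local
  effect is concentrated inside one quartile.
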