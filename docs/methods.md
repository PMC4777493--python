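# Methods

This note documents the models implemented in `osanl`, the choices made
where the procedure is genuinely open, and what the synthetic data does and
does not establish.

## Signals and windowing

A subject-night is three channels: nasal-cannula airflow (default 200 Hz),
thoracic belt excursion (default 10 Hz) and pulse-oximetry SpO2 (default
1 Hz). Sample indexing is 0-based and windows are half-open
`[start, start+duration)` in seconds, so window extraction composes exactly.
Analysis windows start one hour into the recording, past sleep onset and
settling artifacts. The scheme is:

| feature family | signal | window |
|---|---|---|
| DFA flow (`_f`) | airflow | 20 min |
| DFA decimated flow (`_f2`) | airflow, every 4th sample kept | 80 min |
| DFA thoracic (`_t`) | belt | 240 min |
| LLE flow / decimated flow | airflow | 20 min / 80 min |
| LLE thoracic | belt | 170 min |
| ApEn (`_f`, `_t`) | airflow, belt at 1 Hz | whole night |
| T90 | SpO2 | whole night |

The `f2` decimation is literal value-keeping (no anti-alias filter): the
operation *defines* the feature, it is not a resampling step. The decimated
series carries rate/4, so an 80-minute decimated window holds the same
sample count as a 20-minute raw window. EDF and continuous EDF+ files are
supported; discontinuous EDF+D is rejected because every estimator assumes
contiguous time.

## Estimators

**DFA.** The series is mean-subtracted and integrated; the profile is split
into non-overlapping boxes of n samples (trailing partial box discarded); a
least-squares line is removed per box; F(n) is the RMS of the residuals
pooled over boxes. Slopes of log F(n) vs log n are fit over a *fast* band
(8–30 s) and a *slow* band (30–100 s), each with 7 log-spaced box sizes; the
8/30/100 s anchors correspond to roughly 2, 6 and 24 breaths at a 4 s breath
period. A band slope needs at least 3 boxes with F(n) > 0; a zero-variance
series gives F ≡ 0 and is flagged degenerate with NaN slopes rather than
guessed. `alpha_overall` (slope across the full 8–100 s range) is used when
validating against reference series whose scaling is a single power law:
linear detrending, boxes ≥ 8 samples and 20-seed averaging recover
α = H on fractional Gaussian noise to within 0.07 for H ∈ [0.3, 0.9]
(n = 16384), and α = 0.5 on white noise within 0.05.

**ApEn.** Pincus convention with self-matches: Φ_m = mean_i log(C_i^m /
(N−m+1)) with C_i the count of length-m templates within Chebyshev distance
r of template i, and ApEn = Φ_m − Φ_{m+1}; m = 2, r = 0.2 × SD of the whole
series. Counting uses a k-d tree, which is exact — the implementation
equals a direct O(N²) counting oracle bit-for-bit. Because an O(N²)-defined
statistic over a full night at 200 Hz (~4M samples) is not meaningful to
compute directly, the whole-night signals are reduced to 1 Hz by
within-second means before ApEn; this preserves the breath-to-breath
regularity structure the statistic is meant to sense (a 4 s breath is still
resolved at 1 Hz as a period-4 pattern). The rate is configurable. A
constant series returns ApEn = 0 (every epoch matches every other, the
conditional probability is 1); the tolerance factor must be positive.

`APEN_high`/`APEN_low` are defined here as the max/min of the first
differences of ApEn computed over successive non-overlapping 5-minute
sub-windows (same r as the whole series): a signed, near-symmetric measure
of how abruptly regularity changes across the night. The derived pair is
dAPEN = high + low and mAPEN = (high + low)/2. Descriptive tables in the
clinical literature report ApEn-derived quantities at magnitudes far above
the mathematical ceiling of canonical ApEn (≈ log of the template count),
so no attempt is made to reproduce any particular published scale; the
definition used here is exact and documented.

**LLE.** Rosenstein's method: delay-embed the series (dimension 5 for
respiratory signals, 2 for map references; delay defaulting to the first
zero crossing of the autocorrelation), pair every point with its nearest
neighbor at temporal separation beyond a Theiler window (one breath period
for respiratory signals), and track the mean log distance between pairs
after k steps. λ is the least-squares slope of that divergence curve over
the initial linear region, times the sampling rate (per second; per
iteration for rate-1 map references). When no fit range is given the linear
region is taken as the steps before the curve climbs half of its total rise
— fitting past the plateau where trajectories decorrelate would bias λ
toward 0. Neighbor pairs closer than 1e-8 × SD are rejected: below rounding
error the "divergence" of such pairs is numerical noise (a noiseless
sinusoid sampled at an integer number of cycles otherwise pairs each point
with its exact copy one period away). λ may legitimately be negative for
strongly contracting dynamics. Validation: λ = ln 2 ± 0.05 on the r = 4
logistic map, |λ| ≤ 0.02 per step on a pure sinusoid.

**T90** is the percentage of samples strictly below 90 % saturation.

**Derived parameters.** For each difference/mean pair from components
(X, Y): d = X − Y, m = (X + Y)/2, so X = m + d/2 and Y = m − d/2 exactly.
Pairs: (DFAfast, DFAslow) per signal family, (LLEf, LLEt), (LLEf2, LLEt),
and (mDFA_f2, mDFA_t) for dmDFA_t2/mmDFA_t2. The sign convention
dDFA = DFAfast − DFAslow is the default and is exposed as a flag
(`dfa_diff_sign`), since the opposite order is also seen in the clinical
literature's summary tables.

## Predictive models

**Screening equation.** `AHI = 1.2·BMI + 0.4·T90 − 18.6·dDFA_f2 + 7.8·dLLE
+ 60.5·mmDFA_t2 − 27`, evaluated exactly as an affine form; the output is
not clamped at zero by default because screening cutoffs (5 or 8 events/h)
are applied to the raw affine value. Refitting uses ordinary least squares
with coefficient standard errors, the multiple correlation R and residual
SD; rank-deficient designs are rejected rather than silently regularized.

**Severity.** AHI ≤ 5 normal, (5, 15] mild, (15, 30] moderate, > 30 severe.
The two-group treatment decision (CPAP group) uses AHI ≥ 15; note the band
classifier calls exactly 15 "mild" while the treatment threshold includes
15 — both conventions appear in clinical practice, so the threshold is a
parameter and the discrepancy exists only at the single point 15.

**Decision tree.** C4.5-style: at each node the split maximizing gain ratio
(information gain / split information); numeric splits at midpoints between
adjacent distinct sorted values, categorical features split multiway;
minimum leaf size 2; subtree-replacement pruning using the pessimistic
binomial upper-bound error estimate at confidence 0.25 (the classic C4.5
defaults). Probabilities are raw leaf class frequencies and serve as ROC
scores. Ties between splits break by feature order, making induction
deterministic. Subtree raising is not implemented; pruning is replacement
only.

**Feature selection.** Best-first search over subsets starting from the
empty set, expanding by single-feature additions and removals, scored by
seeded stratified-CV accuracy of the base learner (the gain-ratio tree by
default), stopping after 5 consecutive non-improving expansions. If nothing
beats the majority-class baseline the best single feature is returned.

**Evaluation.** Stratified k-fold (default 10) with shuffled, seeded fold
assignment; folds differ in size by at most one and each sample is tested
exactly once. Metrics come from the pooled out-of-fold confusion matrix:
accuracy, Cohen's kappa, per-class TP/FP rate, precision, recall, F-measure,
and per-class ROC areas from pooled out-of-fold class scores (one-vs-rest,
computed as the tie-aware normalized Mann-Whitney U). If the smallest class
has fewer than k members, k is reduced with a warning.

## Statistics toolkit

Two-group comparisons are normality-gated: a Kolmogorov-Smirnov-type test
on each group (Lilliefors correction by default, since the reference
parameters are estimated; plain KS available), then a pooled-variance
t-test with a 95 % CI of the mean difference if both groups pass at
α = 0.05, else Mann-Whitney U. Pooled rather than Welch is the default to
match the conventional "equality of means" output of clinical statistics
software; Welch is a flag. Sensitivity/specificity treat true AHI ≥ 5 as
disease regardless of the screening cutoff applied to the predicted value.
ROC AUC is the normalized U statistic (exactly the tie-aware trapezoidal
area). Bland-Altman limits are bias ± 1.96 SD of paired differences. The
two-sample power computation uses the two-sided normal approximation
`Φ(δ/(sd·√(1/n1+1/n2)) − z_{1−α/2}) + Φ(−δ/(…) − z_{1−α/2})`, which is
closed-form, monotone in δ and n, and reduces exactly to α at δ = 0 (the
noncentral-t refinement is not needed at the design sample sizes used
here; at δ = 0.15, sd = 0.2, n = 25/75 it gives 0.901). Multiple-testing
correction is deliberately off by default.

## Synthetic data

The generator is the package's study condition, not a tuning knob. One
subject-night is: sinusoidal breathing at a 4 s period in airflow (unit
amplitude) and belt (amplitude 0.8, phase-shifted); events placed by a
Dirichlet-spacing renewal scheme with a minimum one-breath gap and a
120 s event-free margin at both ends — the Dirichlet concentration falls
with AHI, so severe nights have clustered event trains; apneas gate the
airflow envelope to 5 % of baseline (belts persist at 60 %, the paradoxical
obstructive signature), hypopneas to 30–70 %; edges are raised-cosine over
1.5 s. SpO2 rests at 96 %, ramps down starting 10 s after event onset to a
nadir (depth ~N(10, 3) %, clipped to [2, 30]) 5 s past event end, and
recovers exponentially with τ = 15 s. Additive Gaussian noise has SD =
noise_sd × breathing amplitude (default 0.05, a free choice; the noise
floor of real recordings is equipment-specific). A slow random amplitude
modulation (30 s knots) with depth 0.006 × AHI injects severity-dependent
long-range structure; at AHI = 0 with zero noise the airflow is exactly
periodic. Requested event loads that cannot be placed without overlap raise
an error; the default cohort severity mixture (24 % normal, 15 % mild,
18 % moderate, 43 % severe, severe tail capped at 110/h) respects that
feasibility limit for 6 h nights.

Cohorts couple BMI and Epworth score to the standardized true AHI through
a linear Gaussian coupling targeting correlations 0.58 and 0.47, with
population-style marginals (BMI ~N(31.94, 6.89) clipped to [17, 53],
Epworth ~N(7.8, 5.1) rounded and clipped to [0, 24], age ~N(48.4, 13.6)
clipped to [16, 83], 74 % male). Simulated cohorts default to reduced
channel rates (flow 8 Hz, thoracic 2 Hz, SpO2 1 Hz): the estimators are
rate-aware, and these rates keep a 40-subject, 6-hour-per-night pipeline
run to a few minutes on one CPU; full acquisition rates remain the
defaults for real recordings.

**What passing tests do and do not show.** The synthetic signals exercise
the estimators' correctness (validated separately against analytic ground
truth), the exact derived-feature identities, determinism, and the full
plumbing from EDF to cross-validated classification. They do not emulate
real respiratory fractality: a gated sinusoid has near-zero DFA exponents
and its LLE reflects noise-driven divergence, so the *absolute* feature
values — and therefore the screening equation's operating point on
synthetic cohorts — differ from clinical data. In particular, with
population-style BMI (mean ≈ 32) the equation's BMI term alone exceeds the
cutoff-8 screening threshold for most simulated subjects, so synthetic
specificity at that cutoff is poor; this is a property of the simulated
feature scales, not of the equation's implementation. Reference series
(fGn by exact Davies–Harte circulant embedding, logistic map, Lorenz,
sinusoids) carry the quantitative validation burden instead.

## Numerical notes

* EDF is 16-bit; written physical bounds are widened to the exact 8-char
  header representation before digitizing, so a round trip is accurate to
  one quantization step of the channel range.
* fGn synthesis clips tiny negative circulant eigenvalues (round-off) to
  zero; the embedding is otherwise exact for 0 < H < 1.
* DFA box sizes are deduplicated after conversion to samples and require
  ≥ 4 samples per box and 4× coverage of the largest box.
* ApEn at zero spread (r = 0) short-circuits to 0 instead of dividing by a
  zero tolerance.
* The kappa computation rejects degenerate tables with expected agreement 1.

## Known limitations

* The synthetic generator does not model central apneas, sleep staging,
  arousals, cardiac or EEG channels, or realistic breath-to-breath
  fractality (see above).
* ApEn on real 200 Hz full-night signals is defined via the 1 Hz reduction;
  other reductions change the absolute values.
* Decision-tree pruning is subtree replacement only (no raising); trees on
  small cohorts vary with fold seed, which is why evaluation seeds are
  explicit everywhere.
* The Lorenz reference integrates with an adaptive RK45 at tight tolerance;
  bitwise determinism holds for a fixed SciPy version.
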