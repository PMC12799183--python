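# Methods

## The decision model

Each trial presents one of eight digit categories in a 2×2 factorial
design: stimulus difficulty (easy/hard) × speed–accuracy instruction
(speed/accuracy). At every processing step the evidence source emits an
8-dimensional activation vector; a race accumulator integrates each
coordinate independently and decides at the first step at which any
accumulated coordinate reaches the threshold (3.0 under speed
instructions, 6.0 under accuracy instructions). The choice is the crossing
coordinate — among simultaneous crossers, the one with the most
accumulated evidence, with exact ties going to the lowest index — the
response time is the number of steps consumed, and the accumulated vector
**z** at the decision step is the input to every confidence computation.
Accumulators are not floored at zero (activations are logit-like and may
be negative), and a cap of 1,000 steps forces an argmax choice on the rare
trial that never crosses.

## The synthetic evidence source

The per-step evidence for a trial of category *c* in difficulty condition
*d* is

    x_t = γ · a_d · (m_c + u) + σ_step · ε_t,      ε_t ~ N(0, C)

with the following ingredients, all drawn once per trial except the step
noise:

* **Class mean structure** `m_c = s · conf[c, :]`, where `conf` is a
  symmetric confusability matrix with unit diagonal, baseline −0.40 off
  the diagonal (non-target activations drift mildly downward, as logits
  do), and elevated entries for visually similar digit pairs (1↔7 at
  +0.15, 3↔8 at +0.05, 5↔6 at 0.0). The separation scale is s = 1.8
  activation units per step.
* **Difficulty attenuation** `a_d`. Difficulty is a stimulus manipulation
  — pixel noise added to the image — so it attenuates the evidence signal
  divisively rather than inflating the readout noise: the easy condition
  (stimulus-noise amplitude 2.1) is the reference with a = 1, and the hard
  condition (amplitude 4.1) has a = 2.1/4.1 ≈ 0.51. This is what makes
  hard trials slower, less accurate, and lower in decision-stage evidence
  margins. The alternative mapping — scaling the per-step evidence noise
  by the two amplitudes — provably inverts the empirical signatures in a
  threshold race: the decision-step evidence is threshold-pinned plus
  overshoot, overshoot grows with step noise, so "harder" trials would
  show *higher* positive evidence and no margin loss.
* **Clarity gain** `γ`, lognormal with unit mean and sigma 0.6: exemplar
  strength varies multiplicatively across trials. Clean exemplars drive
  large per-step activations and overshoot the threshold by a wide margin;
  murky ones tiptoe to it. This is the mechanism that gives the
  positive-evidence statistic its sensitivity to stimulus quality.
* **Item effect** `u`: a diffuse Gaussian perturbation (SD 0.3) of the
  whole profile plus a pairwise-ambiguity component — between zero and
  three rival categories, drawn uniformly, each boosted by an
  exponential(0.8) amount. A misreadable exemplar is typically ambiguous
  with specific alternatives ("this 1 looks a bit like a 7"), so the
  number of genuinely close rivals varies from trial to trial; that
  variation is what dissociates whole-distribution strategies from
  top-two-margin strategies.
* **Step noise**: SD σ_step = 1.0 per step with spherical structure `C`
  by default, difficulty-independent — it models the stochastic readout
  (weight sampling), which does not depend on the stimulus.

The free constants (separation 1.8, gain sigma 0.6, item SD 0.3, ambiguity
scale 0.8 with up to 3 rivals) were calibrated once, before any
model-comparison experiment, against pre-stated targets: easy-condition
accuracy in the 0.8–0.9 band, hard below easy, the higher threshold at
least as accurate as the lower, and plausible multi-step response times.
Under the defaults the simulated task yields easy accuracy 0.79/0.86
(speed/accuracy threshold) with mean RT 2.7/5.2 steps, and hard accuracy
0.64/0.77 with mean RT 3.9/8.7 steps.

What the generator does **not** emulate: real image content (there are no
pixels anywhere), learned inter-category structure beyond the stipulated
confusability matrix, sequential effects or lapses, and realistic RT
distributions in milliseconds (RT exists only as a step count). Passing
tests therefore show that the fitting and comparison machinery behaves
correctly on data whose generative structure is known — not that any
particular strategy describes human confidence.

## Confidence strategies

All seven strategies read the decision-step vector **z**; `chosen` is
always the race winner. PE and Top2Diff scores are divided by the standard
deviation (ddof = 1) of the pooled raw scores of the whole simulation run,
one SD per strategy, all conditions together. Softmax is computed with
max-subtraction. The posterior model fits one mean vector and one
covariance matrix per category (sample moments of a labeled calibration
pool of decision-step vectors, racing fresh evidence mixed evenly over the
four condition cells; 300 vectors per category per cell by default) with a
ridge of 1e-6 × the mean diagonal variance added to each covariance;
posteriors are evaluated in log space through Cholesky factors and
normalized with log-sum-exp. Entropy uses the natural log; the log base
only rescales the confidence variable and the criterion fit absorbs any
monotone rescaling. "Second most probable choice" in ProbTop2Diff means
the best *non-chosen* posterior, so the value goes negative when the race
winner is not the posterior argmax.

### An exact equivalence, and a near one

Because the posterior sums to one, ProbAvgRes confidence equals
(8·BCH − 1)/7 — an increasing affine transform. Criterion refitting
absorbs any such transform, so **BCH and ProbAvgRes are observationally
equivalent** in this framework: their fitted log-likelihoods coincide to
floating-point jitter on every dataset. Model-recovery winners are
therefore reported with an AIC tie tolerance of 0.1 points, two orders of
magnitude below any difference treated as evidence.

Softmax and Top2Diff are *nearly* equivalent for a subtler reason: the
softmax of the decision-step evidence is dominated by exp(−margin), so it
is close to a fixed monotone transform of the top-two margin (Spearman
ρ ≈ 0.99 under every generator variant examined). At 4-point rating
resolution their predicted response distributions differ by under one AIC
point per 960-trial subject — compared with 15–40 points for every other
strategy pair. Distinguishing them in a 20-subject recovery study
consequently requires the pooled model run to be large enough that
response-matrix estimation error is negligible at sub-AIC-point scale;
the default pool is 60 instances × 1,920 trials = 460,800 trials, sized
by measuring the finite-pool bias directly (−0.6 AIC/subject at 57,600
trials, undetectable at 460,800). This near-equivalence is a substantive
property of criterion-binning comparisons, worth keeping in mind when
interpreting small Softmax–Top2Diff AIC differences.

## Criterion fitting

The three criteria map continuous confidence onto ratings by the
half-open rule: rconf ∈ [cᵢ₋₁, cᵢ) → rating *i* (so a value exactly at a
criterion takes the higher rating). The response matrix bins the pooled
model trials by stimulus, choice, and rating; probabilities are
normalized within each stimulus slice, since stimuli are
experimenter-controlled and the model predicts (choice, rating)
conditional on the stimulus. Cells are floored at ε = 1/(2 × pool size)
inside the log — a continuity correction for cells left empty by finite
pooling. The subject log-likelihood is Σ nᵢⱼₖ log pᵢⱼₖ with zero-count
cells contributing zero.

The likelihood is piecewise constant in the criteria — it changes only
when a criterion crosses one of the pooled raw-confidence values — so the
MLE search works over the finite set of bin boundaries (midpoints between
consecutive distinct values, plus sentinels below and above the range).
Small candidate sets (≤ 66) are enumerated exhaustively; larger ones get
a coarse-grid full-triple enumeration followed by coordinate-wise
exhaustive refinement over the full candidate set, which terminates
because every accepted move strictly improves the likelihood. Candidate
sets above 2,048 boundaries are thinned to evenly spaced quantiles; the
plateaus skipped are narrower than 1/2048 of the pooled distribution.
Exhaustive enumeration doubles as the exactness oracle in the tests: on a
30-trial pool the search ties the enumerated optimum to 1e-9.

A noise-floor note on criterion recovery: a subject contributes 960
trials, so the MLE can locate a criterion only as precisely as the
subject's realized rating marginals, which deviate from the generating
proportions by binomial noise with SD ≈ √(p(1−p)/960) ≈ 1.6 percentage
points. Recovery is therefore assessed at the cohort level (proportions
averaged over 20 subjects, within 2 points of the generating values per
condition cell); single-subject maxima brush 2–3 points by construction,
and no estimator can do better.

## Model comparison and qualitative analyses

Per-subject AICs (k = 3 always) are compared as mean differences with
percentile-bootstrap 95% CIs over subjects (10,000 resamples, seeded) and
converted to relative likelihoods by exp(ΔAIC/2). Qualitative analyses
compute per-subject mean confidence by condition cell; the folded-X
analysis crosses accuracy with difficulty and reports the two directional
contrasts (easy − hard for correct and for error trials), leaving a
contrast undefined rather than imputing when a cell is empty. Pattern
mismatch is summarized as per-subject sums of squared errors with
two-sided paired t-tests (df = subjects − 1); zero-variance difference
vectors are flagged degenerate with t = 0. Category-wise prediction fits
a linear mixed model (human confidence ~ model confidence, random
intercept per stimulus category, ML estimation via statsmodels MixedLM),
generates fixed-effect predictions, and correlates them with the
observations over all subject × category points; competing correlations
sharing the observed variable are compared with the Fisher-transformed
z-test of Meng, Rosenthal & Rubin (1992), cross-checked against a
bootstrap in the tests.

On the simulated cohorts the expected signatures hold: every strategy
predicts lower confidence for hard than easy stimuli and higher confidence
under the accuracy than the speed instruction; the folded-X contrasts have
the expected signs for the margin- and posterior-based strategies, while
positive evidence shows a flat-to-inverted error branch and softmax a
near-flat one — the same strategies whose error-trial behavior is the
qualitative outlier in human comparisons.

## Degenerate inputs and numerical policy

Ordered criteria are enforced at construction; non-finite confidence
values, empty traces, non-positive thresholds, unknown strategy names,
out-of-range categories and ratings are rejected with diagnostics (CSV
validation reports the offending line). A raw-confidence pool with a
single distinct value cannot anchor criteria and is rejected. Posterior
covariances must be positive-definite after the ridge; the race requires
finite evidence. Zero step noise, zero gain spread, and zero item
variability are allowed as deterministic limits and are used by the
exactness tests.

## Default problem sizes

Pooled run: 60 instances × 4 cells × 8 categories × 240 reps = 460,800
trials (sized as described above). Cohorts: 20 subjects × 960 trials
(4 cells × 8 categories × 30 reps), criteria at mildly jittered quantiles
(8%, 25%, 50%) of the pooled raw confidence, giving a top-heavy rating
distribution like typical human confidence data. Calibration: 300 vectors
per category per condition cell. The unit-test suite uses much smaller
versions of the same objects; the acceptance script and the end-to-end
tests run the full sizes in roughly a minute each.
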