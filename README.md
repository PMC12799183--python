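# raceconf

How do people compute confidence when choosing among many alternatives?
`raceconf` is a simulation-and-model-comparison pipeline for that question,
built around an 8-alternative digit-discrimination task. A stochastic
evidence source (a parametric stand-in for a neural network's output layer)
feeds a race accumulator: evidence for each of the eight options is
integrated independently until one accumulator reaches a threshold, which
fixes the choice, the response time, and the decision-step evidence vector
**z** = [z₁ … z₈]. From **z** the package derives trial-level confidence
under seven candidate strategies, fits each strategy to discrete 1–4
confidence ratings by maximum likelihood, and compares strategies by AIC
and by qualitative signatures of confidence.

The seven strategies, in the field's notation:

| strategy | definition | reads |
|---|---|---|
| PE (positive evidence) | max(z) / sd | chosen option's raw evidence |
| Top2Diff | (max(z) − max₂(z)) / sd | margin between the two best options |
| Softmax | max softmax(z) | whole raw-evidence distribution |
| BCH (Bayesian confidence hypothesis) | p(chosen) | chosen option's posterior |
| ProbTop2Diff | p(chosen) − max p(others) | top-two posterior margin |
| ProbAvgRes | p(chosen) − mean p(others) | posterior vs the residual |
| Entropy | −H(p) | whole posterior distribution |

Posteriors come from class-conditional multivariate-normal likelihoods
N(μᵢ, Σᵢ) fitted to a labeled calibration pool of accumulated-evidence
vectors, combined with a uniform prior over the eight categories. Ratings
arise from three ordered criteria c₁ ≤ c₂ ≤ c₃: raw confidence in
[cᵢ₋₁, cᵢ) maps to rating *i* (c₀ = −∞, c₄ = +∞). The criteria are the
only fitted parameters (k = 3), estimated by maximizing
Σᵢⱼₖ nᵢⱼₖ log pᵢⱼₖ over an 8 (stimulus) × 8 (choice) × 4 (rating) response
matrix; model comparison uses AIC = −2 log L + 2k, and AIC differences
convert to relative likelihoods via exp(ΔAIC / 2).

The experiment layout is a 2×2 factorial: stimulus difficulty (easy/hard,
implemented as stimulus-noise attenuation of the evidence signal) crossed
with speed–accuracy instructions (decision thresholds 3 and 6). The
synthetic-subject generator produces cohorts with known generating
strategy and known per-subject criteria, so criterion recovery and model
recovery can be tested against ground truth.

## Worked example

```python
import numpy as np
from raceconf import EvidenceModelParams, pipeline

params = EvidenceModelParams.default(seed=0)
pool = pipeline.simulate_model_pool(params, n_instances=8, pool_reps=30, seed=0)

t = pool.trials
acc = (t.choice == t.stimulus).groupby(t.difficulty).mean()
print(acc.round(3).to_dict())

result = pipeline.recovery_study(params, "pe", n_subjects=5,
                                 pool=pool, seed=1)
print(result.mean_aic.round(1).to_dict())
print("winner:", result.winner)
```

prints (exact values depend only on the seeds):

```
{'easy': 0.815, 'hard': 0.7}
{'pe': 4224.8, 'softmax': 4273.5, 'top2diff': 4280.8, 'entropy': 4297.1,
 'probtop2diff': 4326.9, 'bch': 4328.4, 'probavgres': 4328.4}
winner: pe
```

Hard stimuli are less accurate than easy ones, and a cohort whose ratings
were generated under the positive-evidence strategy is best fit by that
strategy — the recovery check at small scale. BCH and ProbAvgRes sit side
by side: because the posterior sums to one, ProbAvgRes confidence is an
increasing affine transform of BCH confidence, so criterion refitting
makes them observationally equivalent (at full scale they tie to the last
digit). Distinguishing Top2Diff from Softmax, whose predictions are far
closer, needs the full-size pooled run — see `docs/methods.md`.

The full analysis lives in `analysis/01_simulate_cohort.py` through
`analysis/05_category_predictions.py`: simulate the pooled model run and a
20-subject cohort, fit all seven strategies per subject, compare AICs with
bootstrap CIs, reproduce the qualitative patterns (difficulty effect,
speed–accuracy effect, folded-X), and predict category-wise confidence
through a random-intercept mixed model. Each script prints what it found
and writes tables under `results/`. A `raceconf` command-line tool wraps
the same pipeline (`simulate`, `fit`, `compare`, `analyze`, `recover`).

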