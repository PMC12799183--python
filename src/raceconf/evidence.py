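"""Synthetic evidence source, calibration pools, and synthetic subjects.

This module is the parametric stand-in for the stochastic classifier that
feeds the race accumulator.  At every processing step it emits an
8-dimensional activation vector: a per-trial signal (class mean structure,
exemplar item effects and rival-ambiguity boosts, multiplied by a clarity
gain and by the difficulty condition's attenuation) plus additive Gaussian
step noise from the stochastic readout.  It also produces the labeled pools
of accumulated-evidence vectors from which the class-conditional Gaussian
posterior model is estimated, and full synthetic subject datasets whose
4-point confidence ratings are generated under a known strategy and known
criteria — the ground truth for recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import strategies
from .fitting import ConfidenceCriteria, discretize_confidence
from .params import (
    N_CLASSES,
    Difficulty,
    EvidenceModelParams,
    ExperimentDesign,
    TrialStimulus,
)
from .race import DEFAULT_MAX_STEPS


def _rng(rng: np.random.Generator | int | None, fallback_seed: int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(fallback_seed if rng is None else rng)


def sample_item_effect(params: EvidenceModelParams, category: int,
                       rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw the per-trial item effect: a fixed offset of the mean vector.

    Emulates exemplar-level idiosyncrasy, held constant across the steps of
    one trial: a diffuse Gaussian perturbation of every coordinate plus an
    exponential boost to one randomly drawn rival category (a misreadable
    exemplar is typically ambiguous with one specific alternative).
    """
    rng = _rng(rng, params.seed)
    eff = params.item_sd * rng.standard_normal(N_CLASSES)
    if params.ambiguity_scale > 0 and params.ambiguity_max_rivals > 0:
        k = int(rng.integers(params.ambiguity_max_rivals + 1))
        rivals = np.delete(np.arange(N_CLASSES), category - 1)
        for rival in rng.choice(rivals, size=k, replace=False):
            eff[rival] += rng.exponential(params.ambiguity_scale)
    return eff


def sample_trial_gain(params: EvidenceModelParams,
                      rng: np.random.Generator | int | None = None) -> float:
    """Draw the mean-one lognormal clarity gain for one trial."""
    rng = _rng(rng, params.seed)
    if params.gain_sd == 0:
        return 1.0
    return float(np.exp(rng.normal(-0.5 * params.gain_sd ** 2, params.gain_sd)))


def trial_signal(params: EvidenceModelParams, stimulus: TrialStimulus,
                 item_effect: np.ndarray, gain: float) -> np.ndarray:
    """Per-step signal of one trial: gained, attenuated structured mean."""
    mu = params.class_means[stimulus.category - 1] + item_effect
    return gain * params.attenuation(stimulus.difficulty) * mu


def sample_evidence_step(params: EvidenceModelParams, stimulus: TrialStimulus,
                         rng: np.random.Generator | int | None = None,
                         item_effect: np.ndarray | None = None,
                         gain: float | None = None) -> np.ndarray:
    """Draw one per-step evidence vector for a stimulus.

    The sample is the trial's signal — the stimulus category's mean
    activation plus the item effect, multiplied by the clarity gain and the
    difficulty attenuation — plus zero-mean Gaussian step noise.  The item
    effect and gain are drawn fresh when not supplied.
    """
    rng = _rng(rng, params.seed)
    if item_effect is None:
        item_effect = sample_item_effect(params, stimulus.category, rng)
    if gain is None:
        gain = sample_trial_gain(params, rng)
    noise = rng.standard_normal(N_CLASSES)
    chol = params.noise_chol()
    if chol is not None:
        noise = chol @ noise
    return trial_signal(params, stimulus, item_effect, gain) \
        + params.step_noise_sd * noise


def generate_evidence_trace(params: EvidenceModelParams, stimulus: TrialStimulus,
                            max_steps: int,
                            rng: np.random.Generator | int | None = None,
                            item_effect: np.ndarray | None = None,
                            gain: float | None = None) -> np.ndarray:
    """Generate a (max_steps, 8) trace of per-step evidence draws.

    Steps are independent given the trial's item effect and clarity gain,
    which are drawn once (if not supplied) and shared by every step.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = _rng(rng, params.seed)
    if item_effect is None:
        item_effect = sample_item_effect(params, stimulus.category, rng)
    if gain is None:
        gain = sample_trial_gain(params, rng)
    noise = rng.standard_normal((max_steps, N_CLASSES))
    chol = params.noise_chol()
    if chol is not None:
        noise = noise @ chol.T
    return trial_signal(params, stimulus, item_effect, gain) \
        + params.step_noise_sd * noise


@dataclass(frozen=True)
class DecisionBatch:
    """Vectorized race outcomes for a block of trials."""

    choice: np.ndarray        # (n,) int, 1-based
    rt_steps: np.ndarray      # (n,) int
    z: np.ndarray             # (n, 8) accumulated evidence at decision
    hit_threshold: np.ndarray  # (n,) bool; False = forced choice at max_steps


def simulate_decisions(params: EvidenceModelParams, categories: np.ndarray,
                       difficulty: Difficulty, threshold: float,
                       max_steps: int = DEFAULT_MAX_STEPS,
                       rng: np.random.Generator | int | None = None,
                       evidence: np.ndarray | None = None) -> DecisionBatch:
    """Run independent races for many trials of one condition at once.

    Mathematically identical to drawing a full evidence trace per trial and
    running :func:`raceconf.race.run_race` on it, but evidence is sampled
    lazily step by step for the still-running trials only.  ``evidence``
    (n, T, 8) substitutes a precomputed evidence bank for the random draws,
    which pins the batch to the single-trial reference path exactly.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    categories = np.asarray(categories, dtype=int)
    if categories.ndim != 1:
        raise ValueError("categories must be a 1-D array")
    if categories.min(initial=1) < 1 or categories.max(initial=N_CLASSES) > N_CLASSES:
        raise ValueError("categories must be in 1..8")
    rng = _rng(rng, params.seed)
    n = categories.size
    mu = params.class_means[categories - 1]
    if evidence is None:
        eff = params.item_sd * rng.standard_normal((n, N_CLASSES)) \
            if params.item_sd > 0 else np.zeros((n, N_CLASSES))
        max_r = params.ambiguity_max_rivals
        if params.ambiguity_scale > 0 and max_r > 0:
            # rival ranking per trial: random order over the 7 non-target
            # coordinates; the first k get an exponential boost
            k = rng.integers(max_r + 1, size=n)
            order = np.argsort(rng.random((n, N_CLASSES - 1)), axis=1)
            boosts = rng.exponential(params.ambiguity_scale, size=(n, max_r))
            boosts = boosts * (np.arange(max_r) < k[:, None])
            rows = np.repeat(np.arange(n), max_r)
            rival = order[:, :max_r].copy()
            rival[rival >= (categories - 1)[:, None]] += 1
            np.add.at(eff, (rows, rival.ravel()), boosts.ravel())
        if params.gain_sd > 0:
            gain = np.exp(rng.normal(-0.5 * params.gain_sd ** 2,
                                     params.gain_sd, size=n))
        else:
            gain = np.ones(n)
        mu = gain[:, None] * params.attenuation(difficulty) * (mu + eff)
    sd = params.step_noise_sd
    chol = params.noise_chol()
    if evidence is not None:
        evidence = np.asarray(evidence, dtype=float)
        if evidence.shape != (n, max_steps, N_CLASSES):
            raise ValueError("evidence bank must have shape (n, max_steps, 8)")

    cum = np.zeros((n, N_CLASSES))
    choice = np.zeros(n, dtype=int)
    rt = np.zeros(n, dtype=int)
    z = np.zeros((n, N_CLASSES))
    hit = np.zeros(n, dtype=bool)
    active = np.arange(n)
    for t in range(1, max_steps + 1):
        if evidence is None:
            noise = rng.standard_normal((active.size, N_CLASSES))
            if chol is not None:
                noise = noise @ chol.T
            step = mu[active] + sd * noise
        else:
            step = evidence[active, t - 1]
        cum[active] += step
        crossed = cum[active] >= threshold
        done = crossed.any(axis=1)
        if done.any():
            idx = active[done]
            zrow = cum[idx]
            masked = np.where(zrow >= threshold, zrow, -np.inf)
            choice[idx] = masked.argmax(axis=1) + 1
            rt[idx] = t
            z[idx] = zrow
            hit[idx] = True
            active = active[~done]
        if active.size == 0:
            break
    if active.size:
        choice[active] = cum[active].argmax(axis=1) + 1
        rt[active] = max_steps
        z[active] = cum[active]
    return DecisionBatch(choice=choice, rt_steps=rt, z=z, hit_threshold=hit)


@dataclass(frozen=True)
class CalibrationSet:
    """Labeled pool of accumulated-evidence vectors (one label per vector).

    Labels are the TRUE stimulus categories, not the race's choices,
    mirroring the use of labeled held-out stimuli to estimate the
    class-conditional likelihood functions.
    """

    vectors: np.ndarray  # (m, 8)
    labels: np.ndarray   # (m,) int, 1-based

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if vectors.ndim != 2 or vectors.shape[1] != N_CLASSES:
            raise ValueError("vectors must be (m, 8)")
        if labels.shape != (vectors.shape[0],):
            raise ValueError("labels must align with vectors")
        counts = np.bincount(labels, minlength=N_CLASSES + 1)[1:]
        if (counts < N_CLASSES + 2).any():
            raise ValueError(
                "every class needs at least dim + 2 = 10 calibration vectors; "
                f"got per-class counts {counts.tolist()}"
            )
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "labels", labels)


def generate_calibration_set(params: EvidenceModelParams, n_per_class: int,
                             threshold: float, max_steps: int = DEFAULT_MAX_STEPS,
                             difficulty: Difficulty = "easy",
                             rng: np.random.Generator | int | None = None) -> CalibrationSet:
    """Race fresh evidence to the threshold and pool the final z per true class."""
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10 so covariances are estimable")
    rng = _rng(rng, params.seed)
    categories = np.repeat(np.arange(1, N_CLASSES + 1), n_per_class)
    batch = simulate_decisions(params, categories, difficulty, threshold,
                               max_steps=max_steps, rng=rng)
    return CalibrationSet(vectors=batch.z, labels=categories)


def generate_mixed_calibration(params: EvidenceModelParams, n_per_class_per_cell: int,
                               design: ExperimentDesign | None = None,
                               rng: np.random.Generator | int | None = None) -> CalibrationSet:
    """Calibration pool mixed evenly over the 2x2 condition cells.

    The posterior model is applied to decision-step evidence from every
    condition, so it is estimated on the same mixture.
    """
    design = design or ExperimentDesign()
    rng = _rng(rng, params.seed)
    parts = [
        generate_calibration_set(params, n_per_class_per_cell, design.threshold(sat),
                                 max_steps=design.max_steps, difficulty=diff, rng=rng)
        for diff, sat in design.cells()
    ]
    return CalibrationSet(vectors=np.vstack([p.vectors for p in parts]),
                          labels=np.concatenate([p.labels for p in parts]))


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth description of one synthetic subject."""

    subject_id: str
    generative_strategy: str
    true_criteria: ConfidenceCriteria
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generative_strategy not in strategies.STRATEGY_NAMES:
            raise ValueError(
                f"unknown strategy {self.generative_strategy!r}; "
                f"expected one of {strategies.STRATEGY_NAMES}"
            )


def simulate_experiment_trials(params: EvidenceModelParams, design: ExperimentDesign,
                               rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Simulate the balanced 2x2 factorial experiment; returns a trial table.

    Columns: difficulty, sat, stimulus, choice, rt_steps, z1..z8.
    """
    rng = _rng(rng, params.seed)
    frames = []
    for diff, sat in design.cells():
        categories = np.repeat(np.arange(1, N_CLASSES + 1), design.n_reps)
        batch = simulate_decisions(params, categories, diff, design.threshold(sat),
                                   max_steps=design.max_steps, rng=rng)
        cell = pd.DataFrame({
            "difficulty": diff,
            "sat": sat,
            "stimulus": categories,
            "choice": batch.choice,
            "rt_steps": batch.rt_steps,
        })
        for k in range(N_CLASSES):
            cell[f"z{k + 1}"] = batch.z[:, k]
        frames.append(cell)
    return pd.concat(frames, ignore_index=True)


def generate_subject_dataset(spec: SubjectSpec, params: EvidenceModelParams,
                             design: ExperimentDesign,
                             posterior_model: "strategies.PosteriorModel",
                             norm: dict[str, strategies.NormalizationContext] | None = None,
                             ) -> pd.DataFrame:
    """Simulate one synthetic subject's full experiment.

    Each trial is raced to a decision, continuous confidence is computed
    under every strategy, and the generative strategy's confidence is binned
    with the subject's true criteria into the 1-4 rating.

    ``norm`` carries the pooled normalization SDs for the raw-evidence
    strategies; if omitted they are computed from this subject's own trials.
    """
    rng = np.random.default_rng(spec.seed)
    trials = simulate_experiment_trials(params, design, rng=rng)
    trials, _ = strategies.add_confidence_columns(trials, posterior_model, norm=norm)
    raw = trials[f"conf_{spec.generative_strategy}"].to_numpy()
    trials.insert(0, "subject_id", spec.subject_id)
    trials.insert(1, "instance_id", "n/a")
    trials["raw_confidence"] = raw
    trials["rating"] = discretize_confidence(raw, spec.true_criteria)
    return trials
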