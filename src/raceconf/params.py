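"""Parameter containers for the evidence model and the experiment design.

The evidence source is a parametric stand-in for a stochastic classifier's
output layer.  At each processing step it emits an 8-dimensional activation
vector: a structured signal (class mean plus exemplar idiosyncrasies,
multiplied by a per-trial clarity gain) plus zero-mean Gaussian step noise
from the stochastic readout.  Task difficulty is an input manipulation —
pixel noise added to the stimulus — so its parameter attenuates the signal
divisively (a noisier image halves the effective class contrast) while the
readout step noise stays the same; this is what makes harder trials slower,
less accurate, and lower in decision-stage evidence margins, rather than
merely more variable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

N_CLASSES = 8

#: Stimulus noise amplitudes for the two difficulty conditions.  The
#: effective signal in the hard condition is attenuated by
#: NOISE_SD_EASY / NOISE_SD_HARD relative to easy.
NOISE_SD_EASY = 2.1
NOISE_SD_HARD = 4.1

#: Accumulation thresholds for the two speed-accuracy instruction conditions.
THRESHOLD_SPEED = 3.0
THRESHOLD_ACCURACY = 6.0

#: Per-step mean activation of the true category's accumulator in the easy
#: condition (before the trial gain).  Chosen so that easy-condition
#: accuracy lands in the 0.8-0.9 range under the default thresholds.
DEFAULT_MEAN_SCALE = 1.8

#: Lognormal sigma of the per-trial clarity gain: exemplar strength varies
#: multiplicatively across trials (clean exemplars drive large activations
#: and cross the threshold with a wide margin; murky ones tiptoe to it).
DEFAULT_GAIN_SD = 0.6

#: Per-step SD of the readout noise (stochastic-weight variability); does
#: not depend on the stimulus or the difficulty condition.
DEFAULT_STEP_NOISE_SD = 1.0

#: Baseline off-diagonal confusability.  Raw activations behave like
#: logits: non-target categories drift mildly downward, which keeps races
#: from terminating on pure noise and makes integration informative.
DEFAULT_CONFUSABILITY = -0.40

#: Category pairs with elevated confusability (visually similar digits,
#: e.g. 1 and 7), 1-based labels; these receive a higher per-step mean than
#: the baseline, making them the typical confusions.
CONFUSABLE_PAIRS: tuple[tuple[int, int, float], ...] = (
    (1, 7, 0.15),
    (3, 8, 0.05),
    (5, 6, 0.00),
)

Difficulty = Literal["easy", "hard"]
Sat = Literal["speed", "accuracy"]

DIFFICULTIES: tuple[Difficulty, ...] = ("easy", "hard")
SATS: tuple[Sat, ...] = ("speed", "accuracy")


def default_confusability() -> np.ndarray:
    """Symmetric 8x8 confusability matrix with unit diagonal."""
    c = np.full((N_CLASSES, N_CLASSES), DEFAULT_CONFUSABILITY)
    np.fill_diagonal(c, 1.0)
    for a, b, w in CONFUSABLE_PAIRS:
        c[a - 1, b - 1] = c[b - 1, a - 1] = w
    return c


@dataclass(frozen=True)
class EvidenceModelParams:
    """Generative parameters of the per-step evidence source.

    Attributes
    ----------
    class_means
        (8, 8) array; row ``i`` is the easy-condition mean activation
        vector emitted when the true stimulus is category ``i + 1``
        (dimensionless activation units per step).
    noise_sd_easy, noise_sd_hard
        Stimulus (pixel) noise amplitudes of the two difficulty conditions.
        They act divisively on the signal: the per-step mean in condition
        ``diff`` is scaled by ``noise_sd_easy / noise_sd(diff)``, i.e. the
        easy condition is the reference and the hard condition's effective
        contrast shrinks by easy/hard.
    step_noise_sd
        Per-step SD of the additive readout noise (difficulty-independent).
    evidence_cov
        Unit-scale 8x8 positive-semidefinite structure of the step noise;
        ``None`` means spherical.  Actual step-noise covariance is
        ``step_noise_sd**2 * evidence_cov``.
    gain_sd
        Lognormal sigma of the mean-one per-trial clarity gain multiplying
        the whole signal (drawn once per trial, fixed across steps).
    item_sd
        SD of the diffuse item effect: a zero-mean Gaussian offset of the
        signal drawn once per trial (exemplar-specific similarity profile).
    ambiguity_scale
        Scale (exponential) of each rival boost in the ambiguity component
        of the item effect: an exemplar raises the signal of a few randomly
        drawn rival categories ("this 1 looks a bit like a 7").  The number
        of genuinely close rivals then varies across exemplars, which is
        what dissociates whole-distribution strategies from top-two-margin
        strategies.
    ambiguity_max_rivals
        Number of boosted rivals drawn uniformly from 0..max per trial.
    seed
        Default RNG seed for convenience constructors.
    """

    class_means: np.ndarray
    noise_sd_easy: float = NOISE_SD_EASY
    noise_sd_hard: float = NOISE_SD_HARD
    step_noise_sd: float = DEFAULT_STEP_NOISE_SD
    evidence_cov: np.ndarray | None = None
    gain_sd: float = DEFAULT_GAIN_SD
    item_sd: float = 0.3
    ambiguity_scale: float = 0.8
    ambiguity_max_rivals: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.class_means, dtype=float)
        if means.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"class_means must be {(N_CLASSES, N_CLASSES)}, got {means.shape}")
        object.__setattr__(self, "class_means", means)
        if not (0 < self.noise_sd_easy < self.noise_sd_hard):
            raise ValueError(
                "need 0 < noise_sd_easy < noise_sd_hard "
                f"(got {self.noise_sd_easy}, {self.noise_sd_hard})"
            )
        # zero step noise / gain spread are allowed as deterministic limits
        if self.step_noise_sd < 0:
            raise ValueError("step_noise_sd must be non-negative")
        if self.gain_sd < 0:
            raise ValueError("gain_sd must be non-negative")
        if self.item_sd < 0:
            raise ValueError("item_sd must be non-negative")
        if self.ambiguity_scale < 0:
            raise ValueError("ambiguity_scale must be non-negative")
        if not 0 <= self.ambiguity_max_rivals <= N_CLASSES - 1:
            raise ValueError("ambiguity_max_rivals must be in 0..7")
        if len({tuple(row) for row in np.round(means, 12)}) != N_CLASSES:
            raise ValueError("class mean vectors must be distinct across classes")
        if self.evidence_cov is not None:
            cov = np.asarray(self.evidence_cov, dtype=float)
            if cov.shape != (N_CLASSES, N_CLASSES) or not np.allclose(cov, cov.T):
                raise ValueError("evidence_cov must be a symmetric 8x8 matrix")
            if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
                raise ValueError("evidence_cov must be positive semi-definite")
            object.__setattr__(self, "evidence_cov", cov)

    @classmethod
    def default(cls, seed: int = 0, mean_scale: float = DEFAULT_MEAN_SCALE,
                confusability: np.ndarray | None = None, **kwargs) -> "EvidenceModelParams":
        """Build params from a mean-separation scale and a confusability matrix."""
        c = default_confusability() if confusability is None else np.asarray(confusability, float)
        if not np.allclose(c, c.T):
            raise ValueError("confusability must be symmetric")
        return cls(class_means=mean_scale * c, seed=seed, **kwargs)

    def noise_sd(self, difficulty: Difficulty) -> float:
        """Stimulus-noise amplitude of a difficulty condition."""
        if difficulty == "easy":
            return self.noise_sd_easy
        if difficulty == "hard":
            return self.noise_sd_hard
        raise ValueError(f"unknown difficulty {difficulty!r}")

    def attenuation(self, difficulty: Difficulty) -> float:
        """Divisive signal attenuation of a difficulty condition.

        The easy condition is the reference (factor 1); harder conditions
        scale the signal by noise_sd_easy / noise_sd_hard.
        """
        return self.noise_sd_easy / self.noise_sd(difficulty)

    def noise_chol(self) -> np.ndarray | None:
        """Cholesky factor of the unit-scale noise structure (None = spherical)."""
        if self.evidence_cov is None:
            return None
        # allow PSD matrices: add a vanishing jitter before factorisation
        cov = self.evidence_cov + 1e-12 * np.eye(N_CLASSES)
        return np.linalg.cholesky(cov)

    def with_seed(self, seed: int) -> "EvidenceModelParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TrialStimulus:
    """One trial's stimulus: category (1-8) and the 2x2 condition cell."""

    category: int
    difficulty: Difficulty = "easy"
    sat: Sat = "speed"

    def __post_init__(self) -> None:
        if not (1 <= int(self.category) <= N_CLASSES):
            raise ValueError(f"category must be in 1..{N_CLASSES}, got {self.category}")
        if self.difficulty not in DIFFICULTIES:
            raise ValueError(f"unknown difficulty {self.difficulty!r}")
        if self.sat not in SATS:
            raise ValueError(f"unknown sat {self.sat!r}")


def threshold_for(sat: Sat, speed: float = THRESHOLD_SPEED,
                  accuracy: float = THRESHOLD_ACCURACY) -> float:
    if sat == "speed":
        return speed
    if sat == "accuracy":
        return accuracy
    raise ValueError(f"unknown sat {sat!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """Balanced 2x2 factorial layout (difficulty x speed-accuracy).

    ``n_reps`` is the number of trials per category within each condition
    cell, so the total trial count is ``4 * 8 * n_reps``.
    """

    n_reps: int = 30
    threshold_speed: float = THRESHOLD_SPEED
    threshold_accuracy: float = THRESHOLD_ACCURACY
    max_steps: int = 1000

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def n_trials(self) -> int:
        return 4 * N_CLASSES * self.n_reps

    def threshold(self, sat: Sat) -> float:
        return threshold_for(sat, self.threshold_speed, self.threshold_accuracy)

    def cells(self) -> list[tuple[Difficulty, Sat]]:
        return [(d, s) for d in DIFFICULTIES for s in SATS]
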