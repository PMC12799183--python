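"""The seven confidence strategies.

Three strategies read confidence directly off the accumulated raw evidence
``z`` at the decision step:

* ``pe`` (positive evidence): ``max(z)``, the evidence for the chosen
  option alone.
* ``top2diff``: ``max(z) - max2(z)``, the margin between the two strongest
  accumulators.
* ``softmax``: the largest softmax-transformed activation.

Because raw activations are unbounded, the ``pe`` and ``top2diff`` scores
are normalized by the standard deviation of the pooled scores across the
whole simulation run (one SD per strategy).

Four strategies first convert ``z`` into posterior probabilities over the
eight categories using class-conditional multivariate-normal likelihoods
with a uniform prior, then read confidence off the posterior vector ``p``:

* ``bch`` (Bayesian confidence hypothesis): ``p[chosen]``.
* ``probtop2diff``: ``p[chosen] - max(p[not chosen])``.
* ``probavgres``: ``p[chosen] - mean(p[not chosen])``.
* ``entropy``: ``-H(p)`` (natural log), so that confidence increases as the
  posterior concentrates.

``chosen`` is always the race winner, even on trials where it differs from
the argmax of ``z`` or of ``p``: confidence is computed for the decision the
accumulator actually produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .params import N_CLASSES

STRATEGY_NAMES: tuple[str, ...] = (
    "pe", "top2diff", "softmax", "bch", "probtop2diff", "probavgres", "entropy",
)
EVIDENCE_STRATEGIES: tuple[str, ...] = ("pe", "top2diff", "softmax")
POSTERIOR_STRATEGIES: tuple[str, ...] = ("bch", "probtop2diff", "probavgres", "entropy")
#: Strategies whose raw score is divided by a pooled standard deviation.
NORMALIZED_STRATEGIES: tuple[str, ...] = ("pe", "top2diff")

Z_COLUMNS = tuple(f"z{k + 1}" for k in range(N_CLASSES))


@dataclass(frozen=True)
class NormalizationContext:
    """Pooled standard deviation used to rescale an unbounded raw score."""

    sd_raw: float

    def __post_init__(self) -> None:
        if not self.sd_raw > 0:
            raise ValueError(f"sd_raw must be positive, got {self.sd_raw}")


def _check_z(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape != (N_CLASSES,):
        raise ValueError(f"z must be an 8-vector, got shape {z.shape}")
    if not np.isfinite(z).all():
        raise ValueError("z contains non-finite values")
    return z


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (N_CLASSES,):
        raise ValueError(f"p must be an 8-vector, got shape {p.shape}")
    return p


def conf_pe(z: np.ndarray, ctx: NormalizationContext) -> float:
    """Positive-evidence confidence: the winning accumulator's evidence."""
    return float(np.max(_check_z(z))) / ctx.sd_raw


def conf_top2diff(z: np.ndarray, ctx: NormalizationContext) -> float:
    """Margin between the two strongest accumulators."""
    z = _check_z(z)
    top2 = np.partition(z, -2)[-2:]
    return float(top2[1] - top2[0]) / ctx.sd_raw


def conf_softmax(z: np.ndarray) -> float:
    """Largest softmax-transformed activation (shift-invariant, in (0, 1])."""
    z = _check_z(z)
    s = np.exp(z - z.max())
    return float(s.max() / s.sum())


@dataclass(frozen=True)
class PosteriorModel:
    """Class-conditional multivariate-normal likelihood model.

    ``mu[i]`` and ``sigma[i]`` are the mean vector and (ridge-regularized)
    covariance matrix for category ``i + 1``; the prior over categories is
    uniform.  Log-densities are evaluated through Cholesky factors.
    """

    mu: np.ndarray       # (8, 8)
    sigma: np.ndarray    # (8, 8, 8)
    ridge: float = 0.0
    _chol: np.ndarray = field(init=False, repr=False, compare=False)
    _logdet: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("mu must be (8, 8): one 8-vector per class")
        if sigma.shape != (N_CLASSES, N_CLASSES, N_CLASSES):
            raise ValueError("sigma must be (8, 8, 8): one 8x8 matrix per class")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("a class covariance is not positive-definite "
                             "after ridge regularization") from exc
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "_chol", chol)
        logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
        object.__setattr__(self, "_logdet", logdet)

    def log_likelihoods(self, Z: np.ndarray) -> np.ndarray:
        """Per-class MVN log-densities for each row of Z; returns (n, 8)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        out = np.empty((Z.shape[0], N_CLASSES))
        const = -0.5 * N_CLASSES * np.log(2.0 * np.pi)
        for i in range(N_CLASSES):
            dev = Z - self.mu[i]
            # solve L y = dev^T; the Mahalanobis form is then |y|^2
            sol = solve_triangular(self._chol[i], dev.T, lower=True)
            maha = np.sum(sol * sol, axis=0)
            out[:, i] = const - 0.5 * self._logdet[i] - 0.5 * maha
        return out

    def to_json(self, path: str | Path) -> None:
        doc = {"mu": self.mu.tolist(), "sigma": self.sigma.tolist(), "ridge": self.ridge}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "PosteriorModel":
        doc = json.loads(Path(path).read_text())
        return cls(mu=np.asarray(doc["mu"]), sigma=np.asarray(doc["sigma"]),
                   ridge=float(doc["ridge"]))


def fit_posterior_model(cal, ridge: float | None = None) -> PosteriorModel:
    """Estimate per-class means and covariances from a calibration pool.

    ``ridge`` is added to every covariance diagonal; the default is
    ``1e-6 x`` the mean diagonal variance across classes, enough to keep the
    Cholesky factorization stable without visibly moving the densities.
    """
    vectors = np.asarray(cal.vectors, dtype=float)
    labels = np.asarray(cal.labels, dtype=int)
    mu = np.empty((N_CLASSES, N_CLASSES))
    raw_sigma = np.empty((N_CLASSES, N_CLASSES, N_CLASSES))
    for i in range(N_CLASSES):
        rows = vectors[labels == i + 1]
        if rows.shape[0] < 10:
            raise ValueError(f"class {i + 1} has {rows.shape[0]} vectors; need >= 10")
        mu[i] = rows.mean(axis=0)
        raw_sigma[i] = np.cov(rows, rowvar=False, ddof=1)
    if ridge is None:
        ridge = 1e-6 * float(np.mean([np.diagonal(raw_sigma[i]).mean()
                                      for i in range(N_CLASSES)]))
    sigma = raw_sigma + ridge * np.eye(N_CLASSES)
    return PosteriorModel(mu=mu, sigma=sigma, ridge=float(ridge))


def posterior_probs(model: PosteriorModel, z: np.ndarray) -> np.ndarray:
    """Posterior category probabilities for one evidence vector.

    With a uniform prior the posterior is the normalized vector of
    class-conditional densities; computed in log space with log-sum-exp so
    that it sums to one to near machine precision even for extreme z.
    """
    z = _check_z(z)
    return posterior_probs_batch(model, z[None, :])[0]


def posterior_probs_batch(model: PosteriorModel, Z: np.ndarray) -> np.ndarray:
    """Row-wise posterior probabilities; returns (n, 8)."""
    ll = model.log_likelihoods(Z)
    logp = ll - logsumexp(ll, axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def _chosen_index(chosen: int) -> int:
    chosen = int(chosen)
    if not 1 <= chosen <= N_CLASSES:
        raise ValueError(f"chosen must be in 1..{N_CLASSES}, got {chosen}")
    return chosen - 1


def conf_bch(p: np.ndarray, chosen: int) -> float:
    """Posterior probability of the chosen option."""
    return float(_check_p(p)[_chosen_index(chosen)])


def conf_probtop2diff(p: np.ndarray, chosen: int) -> float:
    """Chosen option's posterior minus the best non-chosen posterior.

    Negative when the race's choice is not the posterior argmax.
    """
    p = _check_p(p)
    c = _chosen_index(chosen)
    others = np.delete(p, c)
    return float(p[c] - others.max())


def conf_probavgres(p: np.ndarray, chosen: int) -> float:
    """Chosen option's posterior minus the mean of the remaining seven."""
    p = _check_p(p)
    c = _chosen_index(chosen)
    return float(p[c] - (p.sum() - p[c]) / (N_CLASSES - 1))


def conf_entropy(p: np.ndarray) -> float:
    """Negative Shannon entropy of the posterior (natural log, in [-ln 8, 0])."""
    p = _check_p(p)
    terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(terms.sum())


def compute_all_strategies(z: np.ndarray, chosen: int,
                           ctx: dict[str, NormalizationContext],
                           model: PosteriorModel) -> dict[str, float]:
    """All seven confidence values from one decision-step evidence vector."""
    p = posterior_probs(model, z)
    return {
        "pe": conf_pe(z, ctx["pe"]),
        "top2diff": conf_top2diff(z, ctx["top2diff"]),
        "softmax": conf_softmax(z),
        "bch": conf_bch(p, chosen),
        "probtop2diff": conf_probtop2diff(p, chosen),
        "probavgres": conf_probavgres(p, chosen),
        "entropy": conf_entropy(p),
    }


# ---------------------------------------------------------------------------
# vectorized trial-table helpers


def raw_scores(Z: np.ndarray, strategy: str) -> np.ndarray:
    """Unnormalized per-trial raw score for an evidence-based strategy."""
    Z = np.asarray(Z, dtype=float)
    if strategy == "pe":
        return Z.max(axis=1)
    if strategy == "top2diff":
        top2 = np.partition(Z, N_CLASSES - 2, axis=1)[:, -2:]
        return top2[:, 1] - top2[:, 0]
    raise ValueError(f"no raw score for strategy {strategy!r}")


def normalization_from_pool(Z: np.ndarray) -> dict[str, NormalizationContext]:
    """Pooled-SD normalization contexts for the raw-evidence strategies."""
    return {s: NormalizationContext(sd_raw=float(np.std(raw_scores(Z, s), ddof=1)))
            for s in NORMALIZED_STRATEGIES}


def add_confidence_columns(trials: pd.DataFrame, model: PosteriorModel,
                           norm: dict[str, NormalizationContext] | None = None,
                           ) -> tuple[pd.DataFrame, dict[str, NormalizationContext]]:
    """Append ``conf_<strategy>`` columns for all seven strategies.

    ``trials`` must carry ``z1..z8`` and ``choice``.  Returns the augmented
    table and the normalization contexts used (computed from this table's
    pooled raw scores when not supplied).
    """
    Z = trials.loc[:, list(Z_COLUMNS)].to_numpy(dtype=float)
    chosen = trials["choice"].to_numpy(dtype=int) - 1
    if norm is None:
        norm = normalization_from_pool(Z)
    out = trials.copy()
    out["conf_pe"] = raw_scores(Z, "pe") / norm["pe"].sd_raw
    out["conf_top2diff"] = raw_scores(Z, "top2diff") / norm["top2diff"].sd_raw
    shifted = np.exp(Z - Z.max(axis=1, keepdims=True))
    out["conf_softmax"] = shifted.max(axis=1) / shifted.sum(axis=1)

    P = posterior_probs_batch(model, Z)
    rows = np.arange(len(out))
    p_chosen = P[rows, chosen]
    P_masked = P.copy()
    P_masked[rows, chosen] = -np.inf
    out["conf_bch"] = p_chosen
    out["conf_probtop2diff"] = p_chosen - P_masked.max(axis=1)
    out["conf_probavgres"] = p_chosen - (P.sum(axis=1) - p_chosen) / (N_CLASSES - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)
    out["conf_entropy"] = terms.sum(axis=1)
    return out, norm
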