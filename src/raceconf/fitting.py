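"""Confidence-criterion fitting by maximum likelihood.

A subject's discrete 1-4 confidence ratings are modeled by placing three
ordered criteria on the model's continuous confidence scale.  The pooled
model trials, binned at a candidate criterion triple, yield an
8 (stimulus) x 8 (choice) x 4 (rating) response-probability matrix; the
log-likelihood of the subject's observed response counts under that matrix
is maximized over criterion placements.  Because the likelihood is
piecewise constant in the criteria — it changes only when a criterion
crosses one of the pooled raw-confidence values — the search works over the
finite set of bin boundaries (midpoints between consecutive distinct raw
values): a coarse grid pass followed by coordinate-wise exhaustive
refinement, or full enumeration when the candidate set is small.  Model
comparison uses AIC with k = 3 (the three criteria).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .params import N_CLASSES

N_RATINGS = 4
N_PARAMS = 3

#: Candidate boundaries are subsampled to at most this many; likelihood
#: plateaus skipped by the subsampling are narrower than 1/2048 of the
#: pooled distribution.
MAX_CANDIDATES = 2048
#: Grid size for the coarse full-triple enumeration pass.
COARSE_GRID = 48
#: Candidate counts up to this bound are enumerated exhaustively.
EXHAUSTIVE_LIMIT = 66


@dataclass(frozen=True)
class ConfidenceCriteria:
    """Three ordered cut-points on a strategy's continuous confidence scale.

    Implicit outer criteria are c0 = -inf and c4 = +inf; raw confidence in
    [c_{i-1}, c_i) maps to rating i.
    """

    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        if not (self.c1 <= self.c2 <= self.c3):
            raise ValueError(f"criteria must be ordered, got {(self.c1, self.c2, self.c3)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3], dtype=float)


def discretize_confidence(rconf, criteria: ConfidenceCriteria):
    """Map continuous confidence onto the 1-4 rating scale.

    Half-open convention: rating i covers [c_{i-1}, c_i), so a value exactly
    at criterion c_i receives rating i + 1.
    """
    arr = np.asarray(rconf, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("raw confidence contains non-finite values")
    ratings = 1 + np.searchsorted(criteria.as_array(), arr, side="right")
    if np.isscalar(rconf) or arr.ndim == 0:
        return int(ratings)
    return ratings.astype(int)


@dataclass(frozen=True)
class ResponseMatrix:
    """8 x 8 x 4 stimulus-by-choice-by-rating counts and probabilities.

    Probabilities are normalized within each stimulus slice (stimuli are
    experimenter-controlled, so the model predicts the conditional
    distribution of (choice, rating) given the stimulus).  ``eps`` is the
    floor applied to cells inside the log, a continuity correction for
    cells left empty by finite pooling.
    """

    counts: np.ndarray
    probs: np.ndarray
    eps: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        probs = np.asarray(self.probs, dtype=float)
        shape = (N_CLASSES, N_CLASSES, N_RATINGS)
        if counts.shape != shape or probs.shape != shape:
            raise ValueError(f"response matrix must be {shape}")
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probs", probs)


def _trial_arrays(trials: pd.DataFrame, conf_column: str):
    stim = trials["stimulus"].to_numpy(dtype=int)
    choice = trials["choice"].to_numpy(dtype=int)
    rconf = trials[conf_column].to_numpy(dtype=float)
    if ((stim < 1) | (stim > N_CLASSES)).any() or ((choice < 1) | (choice > N_CLASSES)).any():
        raise ValueError("stimulus and choice must be in 1..8")
    return stim, choice, rconf


def build_response_matrix(pooled_trials: pd.DataFrame, criteria: ConfidenceCriteria,
                          eps: float | None = None,
                          conf_column: str = "raw_confidence") -> ResponseMatrix:
    """Bin pooled model trials into the 8 x 8 x 4 response matrix."""
    stim, choice, rconf = _trial_arrays(pooled_trials, conf_column)
    ratings = discretize_confidence(rconf, criteria)
    counts = np.zeros((N_CLASSES, N_CLASSES, N_RATINGS), dtype=int)
    np.add.at(counts, (stim - 1, choice - 1, ratings - 1), 1)
    slice_totals = counts.sum(axis=(1, 2))
    if (slice_totals == 0).any():
        missing = np.flatnonzero(slice_totals == 0) + 1
        raise ValueError(f"stimulus classes with zero pooled trials: {missing.tolist()}")
    if eps is None:
        eps = 1.0 / (2.0 * len(rconf))
    probs = counts / slice_totals[:, None, None]
    return ResponseMatrix(counts=counts, probs=probs, eps=float(eps))


def tabulate_subject_counts(subject_trials: pd.DataFrame) -> np.ndarray:
    """8 x 8 x 4 observed response counts from a rated trial table."""
    stim = subject_trials["stimulus"].to_numpy(dtype=int)
    choice = subject_trials["choice"].to_numpy(dtype=int)
    rating = subject_trials["rating"].to_numpy(dtype=int)
    if ((rating < 1) | (rating > N_RATINGS)).any():
        raise ValueError("ratings must be in 1..4")
    counts = np.zeros((N_CLASSES, N_CLASSES, N_RATINGS), dtype=int)
    np.add.at(counts, (stim - 1, choice - 1, rating - 1), 1)
    return counts


def log_likelihood(matrix: ResponseMatrix, subject_counts: np.ndarray) -> float:
    """Sum over cells of n_ijk * log(p_ijk), with empty cells floored at eps.

    Cells where the subject has no observations contribute zero regardless
    of the model probability.
    """
    subject_counts = np.asarray(subject_counts)
    if subject_counts.shape != matrix.probs.shape:
        raise ValueError("subject counts and response matrix shapes differ")
    logp = np.log(np.maximum(matrix.probs, matrix.eps))
    return float(np.sum(subject_counts * logp))


def aic(logL: float, k: int = N_PARAMS) -> float:
    """Akaike information criterion, -2 logL + 2k."""
    return -2.0 * logL + 2.0 * k


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood criteria for one strategy and one subject."""

    strategy: str
    criteria: ConfidenceCriteria
    logL: float
    aic: float
    k: int = N_PARAMS
    method: str = ""
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "criteria": list(self.criteria.as_array()),
            "logL": self.logL,
            "aic": self.aic,
            "k": self.k,
            "method": self.method,
            "n_evaluations": self.n_evaluations,
        }


class _CriterionSearch:
    """Precomputed structures for fast likelihood evaluation over cut triples.

    For each of the 64 (stimulus, choice) cells the pooled raw-confidence
    values are sorted once; the count of values below each candidate
    boundary is then a lookup, so evaluating a criterion triple reduces to
    array arithmetic on a (candidates x 64) table.
    """

    def __init__(self, stim, choice, rconf, subject_counts, eps):
        self.n = len(rconf)
        uniq = np.unique(rconf)
        if uniq.size < 2:
            raise ValueError("degenerate raw-confidence pool: all values identical")
        bounds = np.concatenate(([uniq[0] - 1.0],
                                 0.5 * (uniq[:-1] + uniq[1:]),
                                 [uniq[-1] + 1.0]))
        if bounds.size > MAX_CANDIDATES:
            keep = np.unique(np.linspace(0, bounds.size - 1, MAX_CANDIDATES).round().astype(int))
            bounds = bounds[keep]
        self.bounds = bounds
        m = bounds.size

        cell = (stim - 1) * N_CLASSES + (choice - 1)
        self.cell_totals = np.bincount(cell, minlength=N_CLASSES * N_CLASSES).astype(float)
        # L[b, c] = number of pooled values in cell c strictly below bounds[b]
        self.L = np.empty((m, N_CLASSES * N_CLASSES), dtype=float)
        for c in range(N_CLASSES * N_CLASSES):
            vals = np.sort(rconf[cell == c])
            self.L[:, c] = np.searchsorted(vals, bounds, side="left")

        stim_totals = self.cell_totals.reshape(N_CLASSES, N_CLASSES).sum(axis=1)
        if (stim_totals == 0).any():
            raise ValueError("a stimulus class has zero pooled trials")
        self.slice_totals = np.repeat(stim_totals, N_CLASSES)  # per cell
        self.S = subject_counts.reshape(N_CLASSES * N_CLASSES, N_RATINGS)
        self.eps = eps
        self.n_evaluations = 0

    def loglik(self, i1, i2, i3) -> np.ndarray:
        """Vectorized log-likelihood for index triples (arrays of equal length)."""
        i1, i2, i3 = (np.atleast_1d(np.asarray(ix, dtype=int)) for ix in (i1, i2, i3))
        t = i1.size
        self.n_evaluations += t
        bins = np.empty((t, N_RATINGS, N_CLASSES * N_CLASSES))
        L1, L2, L3 = self.L[i1], self.L[i2], self.L[i3]
        bins[:, 0] = L1
        bins[:, 1] = L2 - L1
        bins[:, 2] = L3 - L2
        bins[:, 3] = self.cell_totals - L3
        p = bins / self.slice_totals
        logp = np.log(np.maximum(p, self.eps))
        return np.einsum("tkc,ck->t", logp, self.S)

    def loglik_chunked(self, idx: np.ndarray, chunk: int = 8192) -> np.ndarray:
        out = np.empty(idx.shape[0])
        for lo in range(0, idx.shape[0], chunk):
            part = idx[lo:lo + chunk]
            out[lo:lo + chunk] = self.loglik(part[:, 0], part[:, 1], part[:, 2])
        return out


def fit_criteria(subject_trials: pd.DataFrame, pooled_model_trials: pd.DataFrame,
                 strategy: str, eps: float | None = None) -> FitResult:
    """Maximum-likelihood confidence criteria for one subject and strategy.

    ``pooled_model_trials`` must carry a ``conf_<strategy>`` column (the
    model's continuous confidence under that strategy); ``subject_trials``
    must carry ``stimulus``, ``choice`` and the observed ``rating``.
    """
    conf_column = f"conf_{strategy}"
    stim, choice, rconf = _trial_arrays(pooled_model_trials, conf_column)
    counts = tabulate_subject_counts(subject_trials)
    if eps is None:
        eps = 1.0 / (2.0 * len(rconf))
    search = _CriterionSearch(stim, choice, rconf, counts, eps)
    m = search.bounds.size

    if m <= EXHAUSTIVE_LIMIT:
        idx = np.array(list(combinations_with_replacement(range(m), 3)))
        ll = search.loglik_chunked(idx)
        best = int(np.argmax(ll))
        b1, b2, b3 = idx[best]
        best_ll = float(ll[best])
        method = "exhaustive"
    else:
        grid = np.unique(np.linspace(0, m - 1, COARSE_GRID).round().astype(int))
        idx = np.array(list(combinations_with_replacement(grid.tolist(), 3)))
        ll = search.loglik_chunked(idx)
        best = int(np.argmax(ll))
        b1, b2, b3 = (int(v) for v in idx[best])
        best_ll = float(ll[best])
        # coordinate-wise exhaustive refinement over the full candidate set;
        # each pass can only improve, so this terminates
        improved = True
        while improved:
            improved = False
            for which in range(3):
                cand = np.arange(m)
                if which == 0:
                    trip = (cand, np.full(m, b2), np.full(m, b3))
                    valid = cand <= b2
                elif which == 1:
                    trip = (np.full(m, b1), cand, np.full(m, b3))
                    valid = (cand >= b1) & (cand <= b3)
                else:
                    trip = (np.full(m, b1), np.full(m, b2), cand)
                    valid = cand >= b2
                ll_c = search.loglik(*trip)
                ll_c[~valid] = -np.inf
                j = int(np.argmax(ll_c))
                if ll_c[j] > best_ll + 1e-12:
                    best_ll = float(ll_c[j])
                    if which == 0:
                        b1 = j
                    elif which == 1:
                        b2 = j
                    else:
                        b3 = j
                    improved = True
        method = "grid+coordinate"

    crit = ConfidenceCriteria(*(float(search.bounds[i]) for i in (b1, b2, b3)))
    return FitResult(strategy=strategy, criteria=crit, logL=best_ll,
                     aic=aic(best_ll), method=method,
                     n_evaluations=search.n_evaluations)
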