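"""Race evidence accumulator.

Evidence for each of the eight alternatives is integrated independently
across processing steps; the decision is made at the first step at which any
accumulator reaches the threshold.  The response time is the number of
evidence samples consumed, and the full accumulated-evidence vector ``z`` at
the decision step is retained because every confidence strategy is computed
from it.

Accumulators are not floored at zero: per-step evidence values are raw
activations and may be negative.  If several accumulators cross the
threshold on the same step, the one with the largest accumulated evidence
wins; residual exact ties go to the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .params import N_CLASSES

DEFAULT_MAX_STEPS = 1000


@dataclass(frozen=True)
class DecisionOutcome:
    """Result of one race: choice (1-based), RT in steps, and evidence state."""

    choice: int
    rt_steps: int
    z: np.ndarray
    terminated_by: Literal["threshold", "max_steps"]


def run_race(trace: np.ndarray, threshold: float,
             max_steps: int | None = None) -> DecisionOutcome:
    """Run the race on a precomputed evidence trace.

    Parameters
    ----------
    trace
        (T, 8) array of per-step evidence samples.
    threshold
        Positive decision threshold on the accumulated evidence.
    max_steps
        Cap on the number of steps consumed; defaults to the trace length.
        If no accumulator crosses within the cap, the choice is forced to
        the accumulator with the most evidence at the final step.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != N_CLASSES:
        raise ValueError(f"trace must be (T, {N_CLASSES}), got {trace.shape}")
    if trace.shape[0] < 1:
        raise ValueError("trace must contain at least one step")
    if not np.isfinite(trace).all():
        raise ValueError("trace contains non-finite evidence values")
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")

    n_steps = trace.shape[0] if max_steps is None else min(trace.shape[0], int(max_steps))
    if n_steps < 1:
        raise ValueError("max_steps must be >= 1")

    cum = np.cumsum(trace[:n_steps], axis=0)
    crossed_any = (cum >= threshold).any(axis=1)
    hit = np.flatnonzero(crossed_any)
    if hit.size:
        t = int(hit[0])
        z = cum[t]
        # winner: largest accumulated evidence among the crossers this step;
        # argmax resolves residual exact ties to the lowest index
        masked = np.where(z >= threshold, z, -np.inf)
        choice = int(np.argmax(masked)) + 1
        return DecisionOutcome(choice=choice, rt_steps=t + 1, z=z.copy(),
                               terminated_by="threshold")
    z = cum[n_steps - 1]
    return DecisionOutcome(choice=int(np.argmax(z)) + 1, rt_steps=n_steps,
                           z=z.copy(), terminated_by="max_steps")
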