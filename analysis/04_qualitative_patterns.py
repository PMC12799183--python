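"""Qualitative signatures: difficulty effect, SAT effect, and the folded X.

For each subject and strategy, applies the subject's fitted criteria to the
pooled model run to get the strategy's predicted ratings, then compares the
predicted condition-wise mean confidence against the cohort's observed
(synthetic-subject) confidence: difficulty x SAT means, the folded-X
contrasts, and per-subject sums of squared errors with paired t-tests
between strategies.

Writes results/condition_patterns.csv and results/pattern_sse.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from raceconf import io, stats
from raceconf.fitting import ConfidenceCriteria, discretize_confidence
from raceconf.strategies import STRATEGY_NAMES

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--fits", type=Path, default=Path("results/fits.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

pool = io.read_trials(args.cohort / "model_pool_trials.csv")
subjects = io.read_trials(args.cohort / "subjects.csv")
fits = pd.read_csv(args.fits)

human = stats.condition_means(subjects)
human_fx = stats.folded_x(subjects)

rows, sse_rows = [], []
model_patterns = {}
for strategy in STRATEGY_NAMES:
    pred_frames = []
    for _, fr in fits[fits.strategy == strategy].iterrows():
        crit = ConfidenceCriteria(fr.c1, fr.c2, fr.c3)
        pred = pool[["difficulty", "sat", "stimulus", "choice"]].copy()
        pred["subject_id"] = fr.subject_id
        pred["rating"] = discretize_confidence(
            pool[f"conf_{strategy}"].to_numpy(), crit)
        pred_frames.append(pred)
    predicted = pd.concat(pred_frames, ignore_index=True)
    model_patterns[strategy] = stats.condition_means(predicted)
    res = stats.sse_and_paired_test(human, model_patterns[strategy])
    sse_rows.append({"strategy": strategy, "mean_sse": res.mean_sse})
    fx = stats.folded_x(predicted)
    rows.append({
        "strategy": strategy,
        "easy": predicted.loc[predicted.difficulty == "easy", "rating"].mean(),
        "hard": predicted.loc[predicted.difficulty == "hard", "rating"].mean(),
        "speed": predicted.loc[predicted.sat == "speed", "rating"].mean(),
        "accuracy": predicted.loc[predicted.sat == "accuracy", "rating"].mean(),
        "fx_correct": fx["contrast_correct"].mean(),
        "fx_error": fx["contrast_error"].mean(),
    })

patterns = pd.DataFrame(rows).set_index("strategy").round(3)
sse = pd.DataFrame(sse_rows).set_index("strategy")

# paired comparison of each strategy's SSE against the best one
best = sse["mean_sse"].idxmin()
for strategy in STRATEGY_NAMES:
    if strategy == best:
        sse.loc[strategy, ["t_vs_best", "p_vs_best"]] = (np.nan, np.nan)
        continue
    res = stats.sse_and_paired_test(human, model_patterns[strategy],
                                    other_model=model_patterns[best])
    sse.loc[strategy, ["t_vs_best", "p_vs_best"]] = (res.t, res.p)

args.out.mkdir(parents=True, exist_ok=True)
patterns.to_csv(args.out / "condition_patterns.csv")
sse.round(4).to_csv(args.out / "pattern_sse.csv")

obs = {
    "easy": subjects.loc[subjects.difficulty == "easy", "rating"].mean(),
    "hard": subjects.loc[subjects.difficulty == "hard", "rating"].mean(),
    "speed": subjects.loc[subjects.sat == "speed", "rating"].mean(),
    "accuracy": subjects.loc[subjects.sat == "accuracy", "rating"].mean(),
    "fx_correct": human_fx["contrast_correct"].mean(),
    "fx_error": human_fx["contrast_error"].mean(),
}
print("Observed cohort confidence:", {k: round(v, 3) for k, v in obs.items()})
print("\nModel-predicted patterns per strategy:")
print(patterns)
print("\nPer-subject SSE vs observed condition means "
      f"(best = {best}), with paired t against the best:")
print(sse.round(4))
print("\nEvery strategy should show easy > hard and a folded X "
      "(fx_correct > 0 > fx_error) in the directions the cohort shows.")
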