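"""Category-wise prediction of confidence, split by choice accuracy.

For correct and error trials separately: average observed (cohort)
confidence per subject x stimulus category, average each strategy's
predicted confidence the same way, fit a linear mixed model predicting the
observed values from the predicted ones with a random intercept per
category, and correlate fixed-effect predictions with observations.
Competing strategies' correlations are compared with a dependent-
correlation z-test sharing the observed variable.

Writes results/category_fits.csv.
"""

import argparse
from pathlib import Path

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

subjects["correct"] = subjects.choice == subjects.stimulus
pool["correct"] = pool.choice == pool.stimulus

rows = []
for accuracy, label in ((True, "correct"), (False, "error")):
    obs = (subjects[subjects.correct == accuracy]
           .groupby(["subject_id", "stimulus"], observed=True)["rating"]
           .mean().rename("human_conf").reset_index())
    results = {}
    for strategy in STRATEGY_NAMES:
        preds = []
        for _, fr in fits[fits.strategy == strategy].iterrows():
            crit = ConfidenceCriteria(fr.c1, fr.c2, fr.c3)
            sel = pool[pool.correct == accuracy]
            ratings = discretize_confidence(sel[f"conf_{strategy}"].to_numpy(), crit)
            per_cat = (pd.Series(ratings, index=sel.stimulus.values)
                       .groupby(level=0).mean().rename("model_conf").reset_index()
                       .rename(columns={"index": "stimulus"}))
            per_cat["subject_id"] = fr.subject_id
            preds.append(per_cat)
        table = obs.merge(pd.concat(preds, ignore_index=True),
                          on=["subject_id", "stimulus"])
        fit = stats.categorywise_mixed_model(
            table.rename(columns={"stimulus": "category"}),
            group_col="category")
        results[strategy] = (fit, table)
        rows.append({"accuracy": label, "strategy": strategy,
                     "slope": fit.slope, "intercept": fit.intercept,
                     "pearson_r": fit.pearson_r, "mm_aic": fit.aic,
                     "n_points": fit.n_points})

    # compare each strategy's correlation against the best, sharing the
    # observed confidence variable
    best = max(results, key=lambda s: results[s][0].pearson_r)
    best_fit, best_table = results[best]
    for strategy, (fit, table) in results.items():
        if strategy == best:
            continue
        merged = best_table.merge(table, on=["subject_id", "stimulus"],
                                  suffixes=("_best", "_other"))
        r12 = merged["model_conf_best"].corr(merged["model_conf_other"])
        z, p = stats.compare_dependent_correlations(
            best_fit.pearson_r, fit.pearson_r, float(r12), fit.n_points)
        for row in rows:
            if row["accuracy"] == label and row["strategy"] == strategy:
                row["z_vs_best"], row["p_vs_best"] = z, p
    print(f"{label} trials: best category-wise predictor = {best} "
          f"(r = {best_fit.pearson_r:.3f}, mixed-model AIC = {best_fit.aic:.1f})")

out = pd.DataFrame(rows)
args.out.mkdir(parents=True, exist_ok=True)
out.round(4).to_csv(args.out / "category_fits.csv", index=False)
print("\nPer-strategy category-wise fits:")
print(out.round(3).to_string(index=False))
print(f"\nWrote {args.out / 'category_fits.csv'}")
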