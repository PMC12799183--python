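"""Model-comparison statistics and qualitative confidence signatures.

Covers the downstream analyses of the strategy comparison: AIC differences
with percentile-bootstrap confidence intervals and their conversion to
relative likelihoods, condition-wise mean-confidence patterns (difficulty
and speed-accuracy effects), the folded-X signature (confidence rises with
task ease on correct trials and falls on error trials), sum-of-squared-error
pattern fits with paired t-tests, category-wise prediction of confidence via
a random-intercept linear mixed model, and a z-test for comparing two
dependent correlations that share a variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def relative_likelihood(delta_aic: float) -> float:
    """How many times more likely the better model is, exp(dAIC / 2)."""
    return float(np.exp(delta_aic / 2.0))


@dataclass(frozen=True)
class AICComparison:
    """Mean AIC difference of one strategy against the reference, across subjects."""

    strategy: str
    reference: str
    mean_delta: float
    ci_lower: float
    ci_upper: float
    relative_likelihood: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("strategy", "reference", "mean_delta", "ci_lower", "ci_upper",
                 "relative_likelihood", "n_boot", "seed")}


def compare_models_aic(per_subject_aics: pd.DataFrame, reference_strategy: str,
                       n_boot: int = 10_000, seed: int = 0) -> list[AICComparison]:
    """AIC differences (other - reference) averaged over subjects.

    ``per_subject_aics`` is a subjects x strategies table.  The 95% CI is a
    percentile bootstrap over subjects with replacement; the relative
    likelihood is exp(mean dAIC / 2).
    """
    if reference_strategy not in per_subject_aics.columns:
        raise ValueError(f"reference strategy {reference_strategy!r} not in table")
    if len(per_subject_aics) < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    ref = per_subject_aics[reference_strategy].to_numpy(dtype=float)
    out = []
    n = len(ref)
    for name in per_subject_aics.columns:
        if name == reference_strategy:
            continue
        delta = per_subject_aics[name].to_numpy(dtype=float) - ref
        boot_idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = delta[boot_idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        mean_delta = float(delta.mean())
        out.append(AICComparison(
            strategy=name, reference=reference_strategy, mean_delta=mean_delta,
            ci_lower=float(lo), ci_upper=float(hi),
            relative_likelihood=relative_likelihood(mean_delta),
            n_boot=n_boot, seed=seed,
        ))
    return out


def condition_means(trials: pd.DataFrame, value: str = "rating",
                    by: tuple[str, ...] = ("difficulty", "sat")) -> pd.DataFrame:
    """Per-subject mean confidence for each condition cell.

    Returns a long table with columns subject_id, the grouping factors,
    ``mean_conf`` and ``n``.
    """
    grouped = trials.groupby(["subject_id", *by], observed=True)[value]
    out = grouped.agg(mean_conf="mean", n="size").reset_index()
    return out


def folded_x(trials: pd.DataFrame, value: str = "rating") -> pd.DataFrame:
    """Accuracy x difficulty mean confidence and the folded-X contrasts.

    Returns a per-subject table with mean confidence in the four
    (correct/error x easy/hard) cells and the two directional contrasts
    (easy - hard, separately for correct and error trials).  A contrast
    whose cells are missing (e.g. no error trials) is NaN, never imputed.
    """
    t = trials.copy()
    t["correct"] = (t["choice"] == t["stimulus"])
    cells = (t.groupby(["subject_id", "correct", "difficulty"], observed=True)[value]
             .mean().unstack(["correct", "difficulty"]))
    rows = []
    for subject_id, row in cells.iterrows():
        def cell(correct, diff):
            try:
                v = row[(correct, diff)]
            except KeyError:
                return np.nan
            return float(v) if pd.notna(v) else np.nan
        rec = {
            "subject_id": subject_id,
            "correct_easy": cell(True, "easy"), "correct_hard": cell(True, "hard"),
            "error_easy": cell(False, "easy"), "error_hard": cell(False, "hard"),
        }
        rec["contrast_correct"] = rec["correct_easy"] - rec["correct_hard"]
        rec["contrast_error"] = rec["error_easy"] - rec["error_hard"]
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairedTestResult:
    sse_per_subject: np.ndarray
    mean_sse: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def sse_and_paired_test(human: pd.DataFrame, model: pd.DataFrame,
                        other_model: pd.DataFrame | None = None,
                        cells: tuple[str, ...] = ("difficulty", "sat"),
                        value: str = "mean_conf") -> PairedTestResult:
    """Per-subject sum of squared errors between pattern summaries.

    ``human`` and ``model`` are long per-subject condition tables as
    produced by :func:`condition_means`.  If ``other_model`` is given, the
    paired t-test (two-sided, df = n_subjects - 1) compares the per-subject
    SSEs of ``model`` against those of ``other_model``; otherwise it tests
    the model SSEs against zero.  Zero-variance differences are flagged
    degenerate with t = 0.
    """
    def sse_per_subject(m: pd.DataFrame) -> pd.Series:
        keys = ["subject_id", *cells]
        merged = human.merge(m, on=keys, suffixes=("_h", "_m"))
        if len(merged) != len(human):
            raise ValueError("human and model pattern tables do not align")
        merged["sq"] = (merged[f"{value}_h"] - merged[f"{value}_m"]) ** 2
        return merged.groupby("subject_id")["sq"].sum()

    sse = sse_per_subject(model)
    diffs = sse - sse_per_subject(other_model) if other_model is not None else sse
    diffs = diffs.to_numpy(dtype=float)
    n = diffs.size
    if np.allclose(diffs.std(ddof=1) if n > 1 else 0.0, 0.0):
        return PairedTestResult(sse_per_subject=sse.to_numpy(), mean_sse=float(sse.mean()),
                                t=0.0, df=n - 1, p=1.0, degenerate=True)
    t, p = sps.ttest_1samp(diffs, 0.0)
    return PairedTestResult(sse_per_subject=sse.to_numpy(), mean_sse=float(sse.mean()),
                            t=float(t), df=n - 1, p=float(p))


@dataclass(frozen=True)
class MixedModelFit:
    """Random-intercept mixed-model fit of human on model category confidence."""

    slope: float
    intercept: float
    group_var: float
    aic: float
    predictions: np.ndarray
    observed: np.ndarray
    pearson_r: float
    n_points: int

    @property
    def df_correlation(self) -> int:
        # df convention for the prediction-observation correlation
        return self.n_points - 1


def categorywise_mixed_model(table: pd.DataFrame,
                             human_col: str = "human_conf",
                             model_col: str = "model_conf",
                             group_col: str = "category") -> MixedModelFit:
    """Predict human category-wise confidence from a model's, with a
    random intercept per stimulus category.

    ``table`` is long with one row per subject x category.  Predictions use
    the fixed effects (intercept + slope * model confidence); the returned
    Pearson r correlates predictions with observations over all points.
    """
    import statsmodels.formula.api as smf

    data = table.rename(columns={human_col: "_y", model_col: "_x",
                                 group_col: "_g"})[["_y", "_x", "_g"]].dropna()
    if data["_g"].nunique() < 2:
        raise ValueError("need at least two categories with data")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("_y ~ _x", data, groups=data["_g"]).fit(reml=False)
    slope = float(fit.params["_x"])
    intercept = float(fit.params["Intercept"])
    pred = intercept + slope * data["_x"].to_numpy()
    obs = data["_y"].to_numpy()
    r = float(np.corrcoef(pred, obs)[0, 1])
    return MixedModelFit(slope=slope, intercept=intercept,
                         group_var=float(fit.cov_re.iloc[0, 0]),
                         aic=float(-2.0 * fit.llf + 2.0 * (fit.df_modelwc)),
                         predictions=pred, observed=obs, pearson_r=r,
                         n_points=len(data))


def compare_dependent_correlations(r1: float, r2: float, r12: float, n: int
                                   ) -> tuple[float, float]:
    """Two-sided z-test for two dependent correlations sharing one variable.

    ``r1`` and ``r2`` correlate the shared variable with each of two
    others; ``r12`` is the correlation between those two others; ``n`` is
    the number of observations.  Uses the Fisher-transformed statistic of
    Meng, Rosenthal & Rubin (1992), a Steiger-type test:

        rbar2 = (r1^2 + r2^2) / 2
        f = min(1, (1 - r12) / (2 (1 - rbar2)))
        h = (1 - f * rbar2) / (1 - rbar2)
        z = (atanh(r1) - atanh(r2)) * sqrt((n - 3) / (2 (1 - r12) h))
    """
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must be strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise ValueError("need n > 3")
    if r1 == r2:
        return 0.0, 1.0
    rbar2 = (r1 ** 2 + r2 ** 2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
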