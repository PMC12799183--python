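"""Model-comparison statistics and qualitative signatures."""

import numpy as np
import pandas as pd
import pytest

from raceconf import stats


class TestRelativeLikelihood:
    def test_zero_difference_means_equally_likely(self):
        assert stats.relative_likelihood(0.0) == 1.0

    def test_log_consistency(self, rng):
        for d in rng.uniform(-30, 90, size=20):
            assert np.log(stats.relative_likelihood(d)) == pytest.approx(d / 2)


class TestCompareModelsAic:
    def _table(self, rng, n=30, shift=0.0):
        return pd.DataFrame({
            "a": rng.normal(100, 5, size=n),
            "b": rng.normal(100 + shift, 5, size=n),
        })

    def test_identical_distributions_center_on_zero(self, rng):
        table = self._table(rng, n=200, shift=0.0)
        (comp,) = stats.compare_models_aic(table, "a", n_boot=2000, seed=3)
        assert comp.ci_lower < 0 < comp.ci_upper
        assert comp.relative_likelihood == pytest.approx(
            np.exp(comp.mean_delta / 2))

    def test_mean_delta_is_other_minus_reference(self, rng):
        table = self._table(rng, n=100, shift=12.0)
        (comp,) = stats.compare_models_aic(table, "a", n_boot=500, seed=3)
        assert comp.mean_delta == pytest.approx(
            (table["b"] - table["a"]).mean())
        assert comp.ci_lower <= comp.mean_delta <= comp.ci_upper

    def test_bootstrap_ci_shrinks_with_more_subjects(self, rng):
        widths = []
        for n in (10, 160):
            table = self._table(np.random.default_rng(5), n=n, shift=5.0)
            (comp,) = stats.compare_models_aic(table, "a", n_boot=3000, seed=9)
            widths.append(comp.ci_upper - comp.ci_lower)
        assert widths[1] < widths[0]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_models_aic(pd.DataFrame({"a": [1.0], "b": [2.0]}), "a")


def trials_frame(records):
    return pd.DataFrame(records, columns=[
        "subject_id", "difficulty", "sat", "stimulus", "choice", "rating"])


class TestConditionMeans:
    FIXTURE = trials_frame([
        ("s1", "easy", "speed", 1, 1, 4), ("s1", "easy", "speed", 2, 2, 2),
        ("s1", "easy", "accuracy", 3, 3, 3), ("s1", "easy", "accuracy", 4, 4, 4),
        ("s1", "hard", "speed", 5, 5, 1), ("s1", "hard", "speed", 6, 6, 2),
        ("s1", "hard", "accuracy", 7, 7, 3), ("s1", "hard", "accuracy", 8, 1, 2),
        ("s2", "easy", "speed", 1, 1, 4), ("s2", "easy", "speed", 2, 7, 4),
        ("s2", "hard", "speed", 3, 3, 1), ("s2", "hard", "accuracy", 4, 4, 3),
    ])

    def test_hand_computed_cell_means(self):
        out = stats.condition_means(self.FIXTURE)
        cell = out.set_index(["subject_id", "difficulty", "sat"])["mean_conf"]
        assert cell[("s1", "easy", "speed")] == pytest.approx(3.0)
        assert cell[("s1", "hard", "accuracy")] == pytest.approx(2.5)
        assert cell[("s2", "easy", "speed")] == pytest.approx(4.0)

    def test_counts_conserved(self):
        out = stats.condition_means(self.FIXTURE)
        assert out["n"].sum() == len(self.FIXTURE)

    def test_constant_ratings_give_constant_means(self):
        t = self.FIXTURE.assign(rating=4)
        out = stats.condition_means(t)
        assert (out["mean_conf"] == 4.0).all()


class TestFoldedX:
    def test_constructed_signs(self):
        rows = []
        for diff, correct, rating in [
            ("easy", True, 4), ("hard", True, 3),
            ("easy", False, 1), ("hard", False, 2),
        ]:
            for i in range(3):
                stim = 1
                choice = 1 if correct else 2
                rows.append(("s1", diff, "speed", stim, choice, rating))
        fx = stats.folded_x(trials_frame(rows))
        assert fx.loc[0, "contrast_correct"] > 0
        assert fx.loc[0, "contrast_error"] < 0

    def test_missing_error_cell_is_nan_not_imputed(self):
        rows = [("s1", "easy", "speed", 1, 1, 4), ("s1", "hard", "speed", 1, 1, 3),
                ("s1", "hard", "speed", 1, 2, 2)]
        fx = stats.folded_x(trials_frame(rows))
        assert np.isnan(fx.loc[0, "contrast_error"])
        assert fx.loc[0, "contrast_correct"] == pytest.approx(1.0)


class TestSseAndPairedTest:
    def _patterns(self, values_by_subject):
        rows = []
        for sid, cells in values_by_subject.items():
            for (diff, sat), v in cells.items():
                rows.append({"subject_id": sid, "difficulty": diff,
                             "sat": sat, "mean_conf": v, "n": 10})
        return pd.DataFrame(rows)

    def test_identical_patterns_flagged_degenerate(self):
        human = self._patterns({"s1": {("easy", "speed"): 3.0},
                                "s2": {("easy", "speed"): 3.5}})
        res = stats.sse_and_paired_test(human, human)
        assert res.mean_sse == 0.0
        assert res.degenerate and res.t == 0.0

    def test_hand_computed_sse(self):
        human = self._patterns({"s1": {("easy", "speed"): 3.0, ("hard", "speed"): 2.0},
                                "s2": {("easy", "speed"): 4.0, ("hard", "speed"): 3.0}})
        model = self._patterns({"s1": {("easy", "speed"): 4.0, ("hard", "speed"): 1.0},
                                "s2": {("easy", "speed"): 4.0, ("hard", "speed"): 3.0}})
        res = stats.sse_and_paired_test(human, model)
        np.testing.assert_allclose(np.sort(res.sse_per_subject), [0.0, 2.0])
        assert res.mean_sse == pytest.approx(1.0)
        assert res.df == 1

    def test_equal_sse_comparison_gives_zero_t(self):
        human = self._patterns({"s1": {("easy", "speed"): 3.0},
                                "s2": {("easy", "speed"): 3.5}})
        model = self._patterns({"s1": {("easy", "speed"): 3.2},
                                "s2": {("easy", "speed"): 3.7}})
        res = stats.sse_and_paired_test(human, model, other_model=model)
        assert res.t == 0.0 and res.degenerate


class TestMixedModel:
    def _table(self, rng, slope=1.0, intercept=0.0, offsets=None, noise=0.01):
        rows = []
        for s in range(12):
            for cat in range(1, 9):
                x = rng.uniform(2, 4)
                off = 0.0 if offsets is None else offsets[cat - 1]
                y = intercept + slope * x + off + rng.normal(0, noise)
                rows.append({"subject": s, "category": cat,
                             "model_conf": x, "human_conf": y})
        return pd.DataFrame(rows)

    def test_identity_relationship_recovered(self, rng):
        fit = stats.categorywise_mixed_model(self._table(rng))
        assert fit.slope == pytest.approx(1.0, abs=0.02)
        assert fit.intercept == pytest.approx(0.0, abs=0.06)
        assert fit.pearson_r > 0.99
        assert np.isfinite(fit.aic)

    def test_category_offsets_absorbed_by_random_intercepts(self, rng):
        offsets = np.linspace(-0.4, 0.4, 8)
        fit = stats.categorywise_mixed_model(self._table(rng, offsets=offsets))
        assert fit.slope == pytest.approx(1.0, abs=0.05)
        assert fit.group_var > 0.01

    def test_correlation_over_all_subject_category_points(self, rng):
        table = self._table(rng)
        fit = stats.categorywise_mixed_model(table)
        assert fit.n_points == len(table) == 96
        assert fit.df_correlation == 95


class TestDependentCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = stats.compare_dependent_correlations(0.6, 0.6, 0.5, 100)
        assert z == 0.0 and p == 1.0

    def test_swap_negates_z(self):
        z1, p1 = stats.compare_dependent_correlations(0.8, 0.6, 0.5, 200)
        z2, p2 = stats.compare_dependent_correlations(0.6, 0.8, 0.5, 200)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.compare_dependent_correlations(1.0, 0.5, 0.3, 50)
        with pytest.raises(ValueError):
            stats.compare_dependent_correlations(0.5, 0.4, 0.3, 3)

    def test_against_bootstrap_resampling_oracle(self):
        rng = np.random.default_rng(77)
        n = 300
        shared = rng.normal(size=n)
        a = 0.8 * shared + 0.6 * rng.normal(size=n)
        b = 0.4 * shared + 0.9 * rng.normal(size=n)
        r1 = np.corrcoef(shared, a)[0, 1]
        r2 = np.corrcoef(shared, b)[0, 1]
        r12 = np.corrcoef(a, b)[0, 1]
        z, p = stats.compare_dependent_correlations(r1, r2, r12, n)

        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            boot.append(np.corrcoef(shared[idx], a[idx])[0, 1]
                        - np.corrcoef(shared[idx], b[idx])[0, 1])
        boot = np.asarray(boot)
        # two-sided bootstrap p for the difference being zero
        p_boot = 2 * min((boot <= 0).mean(), (boot >= 0).mean())
        assert z > 0
        assert (p < 0.05) == (p_boot < 0.05)
        assert abs(p - p_boot) < 0.1
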