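"""Synthetic evidence source: generative law, determinism, and validity of
the difficulty and speed-accuracy manipulations."""

import numpy as np
import pandas as pd
import pytest

from raceconf import (
    ConfidenceCriteria,
    EvidenceModelParams,
    ExperimentDesign,
    SubjectSpec,
    TrialStimulus,
    generate_calibration_set,
    generate_evidence_trace,
    generate_subject_dataset,
    sample_evidence_step,
    simulate_decisions,
)
from raceconf.evidence import CalibrationSet
from raceconf.fitting import discretize_confidence
from raceconf.params import N_CLASSES
from raceconf.race import run_race


def noiseless_params(**kwargs):
    """Deterministic evidence: zero step noise and no trial variability."""
    kwargs.setdefault("item_sd", 0.0)
    kwargs.setdefault("ambiguity_scale", 0.0)
    kwargs.setdefault("gain_sd", 0.0)
    kwargs.setdefault("step_noise_sd", 0.0)
    return EvidenceModelParams.default(**kwargs)


class TestSampling:
    def test_zero_noise_returns_class_mean_exactly(self):
        params = noiseless_params()
        stim = TrialStimulus(category=3, difficulty="easy")
        np.testing.assert_array_equal(
            sample_evidence_step(params, stim, rng=0), params.class_means[2])

    def test_empirical_mean_matches_generative_law(self, rng):
        params = EvidenceModelParams.default(item_sd=0.0, ambiguity_scale=0.0)
        stim = TrialStimulus(category=1, difficulty="easy")
        n = 100_000
        draws = generate_evidence_trace(params, stim, n, rng=rng,
                                        item_effect=np.zeros(N_CLASSES), gain=1.0)
        se = params.step_noise_sd / np.sqrt(n)
        np.testing.assert_allclose(draws.mean(axis=0), params.class_means[0],
                                   atol=4 * se)

    def test_hard_condition_attenuates_the_signal(self):
        params = noiseless_params()
        easy = sample_evidence_step(params, TrialStimulus(2, "easy"), rng=0)
        hard = sample_evidence_step(params, TrialStimulus(2, "hard"), rng=0)
        ratio = params.noise_sd_easy / params.noise_sd_hard
        np.testing.assert_allclose(hard, ratio * easy, atol=1e-12)

    def test_seeded_draws_are_bit_identical(self, default_params):
        stim = TrialStimulus(category=5, difficulty="hard")
        a = sample_evidence_step(default_params, stim, rng=99)
        b = sample_evidence_step(default_params, stim, rng=99)
        np.testing.assert_array_equal(a, b)

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            TrialStimulus(category=9)

    def test_invalid_noise_ordering_rejected(self):
        with pytest.raises(ValueError):
            EvidenceModelParams.default(noise_sd_easy=5.0, noise_sd_hard=2.0)
        with pytest.raises(ValueError):
            EvidenceModelParams.default(step_noise_sd=-1.0)


class TestTraces:
    def test_single_step_trace(self, default_params):
        stim = TrialStimulus(category=2)
        trace = generate_evidence_trace(default_params, stim, max_steps=1, rng=3)
        assert trace.shape == (1, N_CLASSES)

    def test_zero_noise_trace_is_constant(self):
        params = noiseless_params()
        trace = generate_evidence_trace(params, TrialStimulus(category=4), 10, rng=0)
        assert np.ptp(trace, axis=0).max() == 0.0

    def test_steps_are_serially_independent(self, rng):
        params = EvidenceModelParams.default(item_sd=0.0, ambiguity_scale=0.0)
        trace = generate_evidence_trace(params, TrialStimulus(category=1), 10_000,
                                        rng=rng, item_effect=np.zeros(N_CLASSES),
                                        gain=1.0)
        for k in range(N_CLASSES):
            x = trace[:, k]
            r = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert abs(r) < 0.05


class TestCalibration:
    def test_counts(self, default_params):
        cal = generate_calibration_set(default_params, n_per_class=10,
                                       threshold=3.0, rng=5)
        assert cal.vectors.shape == (80, N_CLASSES)
        assert np.bincount(cal.labels)[1:].tolist() == [10] * N_CLASSES

    def test_zero_noise_vectors_are_steps_times_mean(self):
        params = noiseless_params()
        cal = generate_calibration_set(params, n_per_class=10, threshold=5.0, rng=0)
        for vec, label in zip(cal.vectors, cal.labels):
            mean = params.class_means[label - 1]
            steps = int(np.ceil(5.0 / mean[label - 1]))
            np.testing.assert_allclose(vec, steps * mean, atol=1e-12)

    def test_class_means_separate_along_own_coordinate(self, default_params):
        cal = generate_calibration_set(default_params, n_per_class=400,
                                       threshold=6.0, rng=6)
        for c in range(1, N_CLASSES + 1):
            centroid = cal.vectors[cal.labels == c].mean(axis=0)
            assert int(np.argmax(centroid)) == c - 1

    def test_underfilled_class_rejected(self):
        with pytest.raises(ValueError):
            CalibrationSet(vectors=np.zeros((8, N_CLASSES)),
                           labels=np.arange(1, 9))


class TestBatchSimulator:
    def test_matches_single_trial_race_on_shared_evidence(self, default_params, rng):
        n, t = 64, 40
        cats = rng.integers(1, 9, size=n)
        bank = rng.normal(0.4, 2.0, size=(n, t, N_CLASSES))
        batch = simulate_decisions(default_params, cats, "easy", 3.0,
                                   max_steps=t, rng=rng, evidence=bank)
        for i in range(n):
            ref = run_race(bank[i], 3.0, max_steps=t)
            assert batch.choice[i] == ref.choice
            assert batch.rt_steps[i] == ref.rt_steps
            np.testing.assert_allclose(batch.z[i], ref.z, atol=1e-10)

    def test_difficulty_manipulation_lowers_accuracy(self, default_params):
        cats = np.tile(np.arange(1, 9), 250)
        acc = {}
        for diff in ("easy", "hard"):
            b = simulate_decisions(default_params, cats, diff, 6.0, rng=21)
            acc[diff] = (b.choice == cats).mean()
        assert acc["hard"] < acc["easy"]

    def test_higher_threshold_does_not_lower_accuracy(self, default_params):
        cats = np.tile(np.arange(1, 9), 250)
        acc = {}
        for thr in (3.0, 6.0):
            b = simulate_decisions(default_params, cats, "easy", thr, rng=22)
            acc[thr] = (b.choice == cats).mean()
        assert acc[6.0] >= acc[3.0]


class TestSubjectDatasets:
    def test_trial_count_and_schema(self, default_params, posterior_model, small_pool):
        spec = SubjectSpec("s1", "top2diff", ConfidenceCriteria(0.1, 0.2, 0.3), seed=4)
        design = ExperimentDesign(n_reps=5)
        df = generate_subject_dataset(spec, default_params, design,
                                      posterior_model, norm=small_pool.norm)
        assert len(df) == 160
        for col in ("subject_id", "difficulty", "sat", "stimulus", "choice",
                    "rt_steps", "raw_confidence", "rating"):
            assert df[col].notna().all()
        assert set(df["rating"]).issubset({1, 2, 3, 4})

    def test_permissive_criteria_give_top_rating_everywhere(self, default_params,
                                                            posterior_model, small_pool):
        spec = SubjectSpec("s2", "softmax",
                           ConfidenceCriteria(-1e9, -1e9, -1e9), seed=4)
        df = generate_subject_dataset(spec, default_params, ExperimentDesign(n_reps=2),
                                      posterior_model, norm=small_pool.norm)
        assert (df["rating"] == 4).all()

    def test_ratings_rebin_from_stored_raw_confidence(self, default_params,
                                                      posterior_model, small_pool):
        crit = ConfidenceCriteria(0.2, 0.5, 1.0)
        spec = SubjectSpec("s3", "top2diff", crit, seed=9)
        df = generate_subject_dataset(spec, default_params, ExperimentDesign(n_reps=3),
                                      posterior_model, norm=small_pool.norm)
        rebinned = discretize_confidence(df["raw_confidence"].to_numpy(), crit)
        np.testing.assert_array_equal(df["rating"].to_numpy(), rebinned)

    def test_seeded_dataset_serializes_identically(self, default_params,
                                                   posterior_model, small_pool):
        spec = SubjectSpec("s4", "bch", ConfidenceCriteria(0.3, 0.6, 0.9), seed=12)
        design = ExperimentDesign(n_reps=2)
        a = generate_subject_dataset(spec, default_params, design,
                                     posterior_model, norm=small_pool.norm)
        b = generate_subject_dataset(spec, default_params, design,
                                     posterior_model, norm=small_pool.norm)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            SubjectSpec("s5", "maxent", ConfidenceCriteria(0, 0, 0))
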