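"""Synthetic EOG generator: task taxonomy, templates, determinism,
dataset structure, and the noise dial."""

import numpy as np
import pytest

from eoghci.features import FEATURE_COLUMNS, extract_features
from eoghci.pipeline import extract_features_frame
from eoghci.preprocess import PreprocessConfig, preprocess_trial
from eoghci.synthetic import (EVENT_TASKS, TASKS, SynthesisError, SynthParams,
                              Task, generate_subject, generate_trial,
                              is_event, read_trials_csv, write_trials_csv)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestTaskTaxonomy:
    def test_eleven_distinct_tasks_eight_events(self):
        assert len(TASKS) == 11
        assert len(set(TASKS)) == 11
        assert sum(is_event(t) for t in TASKS) == 8
        assert {t for t in TASKS if not is_event(t)} == {
            Task.OPEN, Task.CLOSE, Task.STARE}
        assert EVENT_TASKS == frozenset(TASKS[:8])


class TestTemplates:
    def test_stare_without_noise_is_silent(self):
        p = SynthParams(noise_sd=0.0, mains_amplitude=0.0)
        rec = generate_trial(Task.STARE, p, _rng())
        assert np.all(rec.horizontal == 0.0)
        assert np.all(rec.vertical == 0.0)

    @pytest.mark.parametrize("amplitude", [1.0, 2.5])
    def test_right_is_pure_horizontal_step(self, amplitude):
        p = SynthParams(noise_sd=0.0, mains_amplitude=0.0,
                        deflection_amplitude=amplitude)
        rec = generate_trial(Task.RIGHT, p, _rng())
        assert rec.horizontal.max() - rec.horizontal.min() == pytest.approx(
            amplitude, abs=1e-12)
        assert np.all(rec.vertical == 0.0)

    def test_up_left_sign_pattern(self):
        p = SynthParams(noise_sd=0.0, mains_amplitude=0.0)
        rec = generate_trial(Task.UP_LEFT, p, _rng())
        assert rec.horizontal.min() < 0 and rec.horizontal.max() <= 0
        assert rec.vertical.max() > 0 and rec.vertical.min() >= 0

    def test_unknown_task_rejected(self):
        with pytest.raises(SynthesisError):
            generate_trial("wink", SynthParams(), _rng())

    def test_non_finite_params_rejected(self):
        with pytest.raises(SynthesisError):
            generate_trial(Task.RIGHT, SynthParams(noise_sd=float("nan")),
                           _rng())
        with pytest.raises(SynthesisError):
            SynthParams(trial_length=2).validate()


class TestDeterminism:
    def test_same_rng_state_gives_identical_trial(self):
        p = SynthParams(seed=5)
        a = generate_trial(Task.CLOSE, p, _rng(42))
        b = generate_trial(Task.CLOSE, p, _rng(42))
        assert np.array_equal(a.horizontal, b.horizontal)
        assert np.array_equal(a.vertical, b.vertical)

    def test_subject_regeneration_is_bit_identical(self):
        p = SynthParams(seed=7)
        d1 = generate_subject("S3", p)
        d2 = generate_subject("S3", p)
        for r1, r2 in zip(d1.trials, d2.trials):
            assert np.array_equal(r1.horizontal, r2.horizontal)
            assert np.array_equal(r1.vertical, r2.vertical)

    def test_adjacent_seeds_differ(self):
        d1 = generate_subject("S1", SynthParams(seed=3))
        d2 = generate_subject("S1", SynthParams(seed=4))
        assert any(not np.array_equal(a.horizontal, b.horizontal)
                   for a, b in zip(d1.trials, d2.trials))


class TestSubjectDataset:
    def test_110_trials_ten_per_task(self):
        ds = generate_subject("S1", SynthParams(seed=1))
        assert len(ds.trials) == 110
        for task in TASKS:
            sub = [t for t in ds.trials if t.task == task]
            assert len(sub) == 10
            assert sorted(t.trial_index for t in sub) == list(range(1, 11))


class TestClassStructure:
    def test_noise_free_same_task_features_identical(self, noisefree_features):
        for _, grp in noisefree_features.groupby("task"):
            V = grp[FEATURE_COLUMNS].to_numpy()
            assert np.allclose(V, V[0], rtol=0, atol=1e-9)

    def test_noise_free_tasks_pairwise_distinct(self, noisefree_features):
        M = noisefree_features.groupby("task", sort=False)[
            FEATURE_COLUMNS].first().to_numpy()
        D = np.linalg.norm(M[:, None, :] - M[None, :, :], axis=2)
        np.fill_diagonal(D, np.inf)
        assert D.min() > 1.0  # every task pair separated in feature space

    def test_within_task_feature_variance_monotone_in_noise(self):
        """Monte-Carlo over 50 seeds: the noise dial only ever spreads a
        task's feature cloud."""
        config = PreprocessConfig()
        mean_var = []
        for noise in (0.0, 0.05, 0.2):
            feats = []
            for seed in range(50):
                p = SynthParams(noise_sd=noise, seed=seed)
                rec = generate_trial(Task.CLOSE, p, _rng(seed))
                fv = extract_features(preprocess_trial(rec, config))
                feats.append(fv.values)
            mean_var.append(np.var(np.vstack(feats), axis=0).mean())
        assert mean_var[0] <= mean_var[1] <= mean_var[2]


class TestTrialsCsv:
    def test_roundtrip(self, tmp_path):
        ds = generate_subject("S1", SynthParams(seed=2, trial_length=20))
        path = tmp_path / "trials.csv"
        write_trials_csv(ds.trials, path)
        back = read_trials_csv(path)
        assert len(back) == 110
        key = {(r.subject_id, r.task, r.trial_index): r for r in back}
        for rec in ds.trials:
            got = key[(rec.subject_id, rec.task, rec.trial_index)]
            np.testing.assert_allclose(got.horizontal, rec.horizontal)
            np.testing.assert_allclose(got.vertical, rec.vertical)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,task\nS1,right\n")
        with pytest.raises(SynthesisError):
            read_trials_csv(path)
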