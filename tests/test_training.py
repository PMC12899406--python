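"""Subject-wise splitting, physically-constrained augmentation, balancing
and the two-stage optimization loop."""

import numpy as np
import pandas as pd
import pytest

from amwfnet.cwt import ScalogramDataset
from amwfnet.preprocess import smooth_kinematic, _differentiate
from amwfnet.synthetic import CohortSpec, simulate_trial
from amwfnet.training import (AugmentationConfig, SplitSpec, TrainConfig,
                              apply_split, assert_no_leakage, augment_trial,
                              balance_training_set, subject_split, train_stage,
                              train_two_stage)
from amwfnet.network import AmwfnetModel, ModelConfig


def _manifest(n_subjects, scores=None):
    rows = []
    for i in range(n_subjects):
        rows.append({"subject_id": f"P{i:02d}",
                     "score": scores[i] if scores else i % 3})
    return pd.DataFrame(rows)


class TestSubjectSplit:
    def test_forty_subjects_24_8_8(self):
        split = subject_split(_manifest(40), SplitSpec(seed=0))
        assert (len(split["train"]), len(split["val"]), len(split["test"])) == (24, 8, 8)

    def test_partitions_disjoint(self):
        split = subject_split(_manifest(17), SplitSpec(seed=3))
        assert_no_leakage(split)
        assert not split["train"] & split["val"]
        assert not split["train"] & split["test"]
        assert not split["val"] & split["test"]

    def test_deterministic(self):
        a = subject_split(_manifest(10), SplitSpec(seed=7))
        b = subject_split(_manifest(10), SplitSpec(seed=7))
        assert a == b

    def test_rounding_toward_train(self):
        split = subject_split(_manifest(11), SplitSpec(seed=1))
        assert len(split["val"]) == 2 and len(split["test"]) == 2
        assert len(split["train"]) == 7

    def test_stratified_covers_every_score(self):
        scores = [0] * 4 + [1] * 6 + [2] * 10
        manifest = _manifest(20, scores)
        split = subject_split(manifest, SplitSpec(seed=11), stratify=True)
        by = dict(zip(manifest["subject_id"], manifest["score"]))
        for part in ("train", "val", "test"):
            assert {by[s] for s in split[part]} == {0, 1, 2}

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train=0.5, val=0.2, test=0.2)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            subject_split(_manifest(4), SplitSpec(seed=0))

    def test_leakage_assertion_fires(self):
        with pytest.raises(AssertionError):
            assert_no_leakage({"train": {"a"}, "val": {"a"}, "test": set()})


def _train_trial(seed=0, duration=1.0):
    spec = CohortSpec(seed=seed, trial_duration=duration)
    tr = simulate_trial(spec, "S01", 3, 1)
    tr.partition = "train"
    return tr


class TestAugmentation:
    def test_identity_configuration(self):
        tr = _train_trial()
        cfg = AugmentationConfig(noise_sigma_emg=0.0, noise_sigma_kine=0.0)
        out = augment_trial(tr, cfg, np.random.default_rng(0),
                            warp=1.0, scale_emg=1.0, scale_kine=1.0)
        assert np.allclose(out.emg, tr.emg)
        assert np.allclose(out.velocity, tr.velocity)

    def test_warp_scales_both_modalities(self):
        tr = _train_trial()
        cfg = AugmentationConfig(noise_sigma_emg=0.0, noise_sigma_kine=0.0)
        out = augment_trial(tr, cfg, np.random.default_rng(0), warp=0.9)
        assert abs(out.emg.shape[1] - round(0.9 * tr.emg.shape[1])) <= 1
        assert abs(out.velocity.size - round(0.9 * tr.velocity.size)) <= 1

    def test_jerk_recomputed_not_noise_injected(self):
        tr = _train_trial()
        out = augment_trial(tr, AugmentationConfig(), np.random.default_rng(1))
        expected_jerk = smooth_kinematic(
            _differentiate(out.kinematics.acceleration, tr.kine_fs), tr.kine_fs)
        assert np.allclose(out.kinematics.jerk, expected_jerk, atol=1e-10)

    def test_non_training_trial_rejected(self):
        tr = _train_trial()
        tr.partition = "val"
        with pytest.raises(ValueError):
            augment_trial(tr, AugmentationConfig(), np.random.default_rng(0))

    def test_out_of_range_factor_rejected(self):
        tr = _train_trial()
        with pytest.raises(ValueError):
            augment_trial(tr, AugmentationConfig(), np.random.default_rng(0), warp=1.5)

    def test_draws_reproducible(self):
        tr = _train_trial()
        a = augment_trial(tr, AugmentationConfig(), np.random.default_rng(5))
        b = augment_trial(tr, AugmentationConfig(), np.random.default_rng(5))
        assert np.array_equal(a.emg, b.emg)
        assert np.array_equal(a.velocity, b.velocity)


class TestBalancing:
    def _trials(self, counts):
        out = []
        for score, n in counts.items():
            for i in range(n):
                spec = CohortSpec(seed=i, trial_duration=0.6)
                tr = simulate_trial(spec, f"S{score}{i:02d}", 1, score)
                tr.partition = "train"
                out.append(tr)
        return out

    def test_counts_balanced_to_majority(self):
        trials = self._trials({0: 2, 1: 4, 2: 8})
        out = balance_training_set(trials, AugmentationConfig(),
                                   np.random.default_rng(0))
        counts = {s: sum(1 for t in out if t.score == s) for s in (0, 1, 2)}
        assert counts == {0: 8, 1: 8, 2: 8}
        assert sum(t.augmented for t in out) == 10

    def test_already_balanced_no_additions(self):
        trials = self._trials({0: 3, 1: 3, 2: 3})
        out = balance_training_set(trials, AugmentationConfig(),
                                   np.random.default_rng(0))
        assert len(out) == 9

    def test_validation_set_rejected(self):
        trials = self._trials({0: 2, 1: 2, 2: 2})
        trials[0].partition = "val"
        with pytest.raises(ValueError):
            balance_training_set(trials, AugmentationConfig(),
                                 np.random.default_rng(0))


def _toy_dataset(n, seed, size=16, separable=True):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 6, n)
    X = rng.random((n, 11, size, size)).astype(np.float32) * 0.1
    if separable:
        for i, y in enumerate(labels):
            X[i, y % 11, (y * 2) % size:(y * 2) % size + 3, :] += 0.8
    actions = (labels % 2 + 1 + 2 * rng.integers(0, 9, n)).astype(np.int64)
    subjects = np.array([f"S{i % 4}" for i in range(n)], dtype=object)
    return ScalogramDataset(X=X, actions=actions, labels=labels, subjects=subjects)


class TestTrainLoop:
    def test_early_stopping_patience(self):
        """Unlearnable labels stall validation loss; patience halts the stage."""
        tr = _toy_dataset(48, 0, separable=False)
        va = _toy_dataset(24, 1, separable=False)
        model = AmwfnetModel(seed=0)
        cfg = TrainConfig(patience=3, seed=0)
        hist = train_stage(model, tr, va, 1e-3, 50, cfg, np.random.default_rng(0))
        assert len(hist) < 50

    def test_history_fields_and_gate_trajectory(self):
        tr = _toy_dataset(32, 2)
        va = _toy_dataset(16, 3)
        model = AmwfnetModel(seed=0)
        hist = train_stage(model, tr, va, 1e-3, 2, TrainConfig(seed=0),
                           np.random.default_rng(0))
        assert len(hist) <= 2
        for h in hist:
            assert {"epoch", "train_loss", "train_acc", "val_loss", "val_acc",
                    "w_emg", "w_kine"} <= set(h)
            assert h["w_emg"] + h["w_kine"] == pytest.approx(1.0, abs=1e-5)

    def test_empty_dataset_rejected(self):
        ds = _toy_dataset(8, 0)
        empty = ScalogramDataset(X=ds.X[:0], actions=ds.actions[:0],
                                 labels=ds.labels[:0], subjects=ds.subjects[:0])
        with pytest.raises(ValueError):
            train_stage(AmwfnetModel(seed=0), empty, ds, 1e-3, 1,
                        TrainConfig(), np.random.default_rng(0))

    def test_two_stage_runs_and_reports(self):
        p_tr, p_va = _toy_dataset(32, 4), _toy_dataset(16, 5)
        a_tr, a_va = _toy_dataset(32, 6), _toy_dataset(16, 7)
        model = AmwfnetModel(seed=0)
        cfg = TrainConfig(stage1_epochs=1, stage2_epochs=1, seed=0)
        hist = train_two_stage(model, (p_tr, p_va), (a_tr, a_va), cfg)
        assert set(hist) == {"stage1", "stage2"}
        assert len(hist["stage1"]) == 1 and len(hist["stage2"]) == 1

    def test_training_reproducible(self):
        tr, va = _toy_dataset(32, 8), _toy_dataset(16, 9)
        losses = []
        for _ in range(2):
            model = AmwfnetModel(seed=3)
            h = train_stage(model, tr, va, 1e-3, 2, TrainConfig(seed=3),
                            np.random.default_rng(3))
            losses.append([e["train_loss"] for e in h])
        assert losses[0] == losses[1]


def test_apply_split_tags_trials():
    spec = CohortSpec(seed=0, trial_duration=0.6)
    trials = [simulate_trial(spec, sid, 1, 1) for sid in ("A", "B", "C")]
    apply_split(trials, {"train": {"A"}, "val": {"B"}, "test": {"C"}})
    assert [t.partition for t in trials] == ["train", "val", "test"]
    with pytest.raises(KeyError):
        apply_split([simulate_trial(spec, "Z", 1, 1)],
                    {"train": set(), "val": set(), "test": set()})
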