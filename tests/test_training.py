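import dataclasses
import warnings

import numpy as np
import pytest

from pascl import synth, training
from pascl.training import (
    SearchSpace,
    TrainConfig,
    grouped_split,
    make_batches,
    train_model,
)


class TestGroupedSplit:
    def test_twelve_patients_split_7_2_3(self):
        pid = np.repeat(np.arange(12), 4)
        plan = grouped_split(pid, seed=0)
        assert len(plan.train_patients) == 7
        assert len(plan.val_patients) == 2
        assert len(plan.test_patients) == 3

    def test_deterministic_per_seed(self):
        pid = np.repeat(np.arange(12), 3)
        assert grouped_split(pid, seed=5) == grouped_split(pid, seed=5)

    def test_disjoint_patient_sets(self):
        for seed in range(10):
            pid = np.repeat(np.arange(10), 5)
            plan = grouped_split(pid, seed=seed)
            plan.validate()
            all_pats = (
                set(plan.train_patients) | set(plan.val_patients) | set(plan.test_patients)
            )
            assert all_pats == set(range(10))

    def test_all_samples_of_a_patient_share_a_split(self, small_cohort):
        c = small_cohort.subset(small_cohort.system_id == 0)
        plan = grouped_split(c.patient_id, seed=1, labels=c.labels)
        member = plan.membership(c.patient_id)
        for p in np.unique(c.patient_id):
            assert len(set(member[c.patient_id == p])) == 1

    def test_both_classes_present_when_required(self, small_cohort):
        c = small_cohort.subset(small_cohort.system_id == 0)
        plan = grouped_split(c.patient_id, seed=2, labels=c.labels)
        member = plan.membership(c.patient_id)
        for split in ("train", "val", "test"):
            assert np.unique(c.labels[member == split]).size == 2

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="patients"):
            grouped_split(np.array([0, 0, 1, 1, 2]), seed=0)

    def test_no_validation_mode(self):
        pid = np.repeat(np.arange(10), 3)
        plan = grouped_split(pid, seed=0, with_validation=False)
        assert len(plan.train_patients) == 7
        assert len(plan.val_patients) == 0
        assert len(plan.test_patients) == 3


class TestMakeBatches:
    def test_36_samples_batch_8_gives_5_batches(self, rng):
        labels = rng.integers(0, 2, size=36)
        batches = make_batches(labels, 8, rng)
        assert [len(b) for b in batches] == [8, 8, 8, 8, 4]
        assert sorted(np.concatenate(batches)) == list(range(36))

    def test_contrastive_batches_have_no_singleton_class(self, rng):
        for trial in range(20):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            if min(np.bincount(labels, minlength=2)) < 2:
                continue
            batches = make_batches(labels, 8, rng, contrastive=True)
            assert sorted(np.concatenate(batches)) == list(range(n))
            for b in batches:
                counts = np.bincount(labels[b], minlength=2)
                assert not np.any(counts == 1), (trial, labels[b])

    def test_fixed_seed_reproduces_batch_order(self):
        labels = np.tile([0, 1], 18)
        a = make_batches(labels, 8, np.random.default_rng(3), contrastive=True)
        b = make_batches(labels, 8, np.random.default_rng(3), contrastive=True)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_small_contrastive_batch_warns_and_strict_raises(self, rng):
        labels = np.tile([0, 1], 10)
        with pytest.warns(UserWarning):
            make_batches(labels, 2, rng, contrastive=True)
        with pytest.raises(ValueError):
            make_batches(labels, 2, rng, contrastive=True, strict=True)


def _separable_cohort(seed=0):
    """A cohort with a large class separation (easy smoke-test task)."""
    params = {
        0: synth.ClassParams(-2.0, 0.1, 30.0, 0.3),
        1: synth.ClassParams(-1.0, 0.1, 33.0, 0.3, 0.3, 2.0),
    }
    spec = synth.CohortSpec(
        n_patients_per_system=(10,),
        class_params=params,
        patient_effect_sd=0.3,
        noise_sd=0.3,
        seed=seed,
    )
    return synth.generate_cohort(spec)


@pytest.fixture(scope="module")
def easy():
    cohort = _separable_cohort()
    plan = grouped_split(cohort.patient_id, seed=0, labels=cohort.labels)
    return cohort, plan


@pytest.fixture(scope="module")
def tiny():
    cohort = _separable_cohort(seed=1)
    plan = grouped_split(cohort.patient_id, seed=1, labels=cohort.labels)
    return cohort, plan


class TestTrainModel:
    def test_large_separation_reaches_high_training_accuracy(self, easy):
        cohort, plan = easy
        result = train_model("scl_adjust", cohort, plan)
        member = plan.membership(cohort.patient_id)
        pred, _, _ = result.predict(cohort.spectra[member == "train"])
        assert (pred == cohort.labels[member == "train"]).mean() >= 0.95

    def test_history_covers_20_epochs(self, easy):
        cohort, plan = easy
        result = train_model("cnn", cohort, plan)
        assert len(result.history) == 20
        assert np.isfinite(result.history["loss"]).all()

    def test_sc_two_phase_history(self, easy):
        cohort, plan = easy
        result = train_model("sc", cohort, plan)
        phases = result.history["phase"].value_counts()
        assert phases["representation"] == 20
        assert phases["head"] == 20

    def test_seeded_training_is_reproducible(self, easy):
        cohort, plan = easy
        a = train_model("cnn", cohort, plan)
        b = train_model("cnn", cohort, plan)
        for wa, wb in zip(a.model.get_weights(), b.model.get_weights()):
            assert np.array_equal(wa, wb)

    def test_ratio_zero_scl_adjust_matches_cnn_trajectory(self, easy):
        """With ratio 0 the combined loss is plain cross-entropy, so the
        scl_adjust run must reproduce the cnn run exactly under one seed."""
        cohort, plan = easy
        cfg = TrainConfig(lr=0.001, momentum=0.7, batch_size=8, ratio=0.0)
        a = train_model("cnn", cohort, plan, cfg)
        b = train_model("scl_adjust", cohort, plan, cfg)
        assert np.allclose(a.history["loss"], b.history["loss"], atol=1e-6)
        for wa, wb in zip(a.model.get_weights(), b.model.get_weights()):
            assert np.allclose(wa, wb, atol=1e-6)


class TestRandomSearch:
    def test_single_round_returns_that_config(self, tiny):
        cohort, plan = tiny
        space = SearchSpace(n_rounds=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, board = training.random_search(space, cohort, plan, "cnn", seed=0)
        assert len(board) == 1
        assert best.lr == pytest.approx(board.iloc[0]["lr"])

    def test_leaderboard_is_deterministic_and_max_ranked(self, tiny):
        cohort, plan = tiny
        space = SearchSpace(n_rounds=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, b1 = training.random_search(space, cohort, plan, "cnn", seed=4)
            _, b2 = training.random_search(space, cohort, plan, "cnn", seed=4)
        assert b1.equals(b2)
        scores = b1["val_score"].to_numpy()
        assert scores[0] == np.nanmax(scores)

    def test_search_including_default_never_beats_best(self, tiny):
        cohort, plan = tiny
        space = SearchSpace(n_rounds=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, board = training.random_search(
                space, cohort, plan, "cnn", seed=5, include_default=True
            )
        default_row = board[board["round"] == 0]
        assert board.iloc[0]["val_score"] >= float(default_row["val_score"].iloc[0])
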