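"""Splits, task construction, SVM training, metrics, and the trial loop."""

import numpy as np
import pytest

from eegaug import (AugmentMethod, Diagnosis, ExperimentConfig, FeatureMatrix,
                    SplitSpec, SVMSettings, Task, evaluate, make_task,
                    run_experiment, split_data, train_classifier)
from eegaug.evalharness import STUDY_TEST_COMPOSITION, split_indices

from conftest import make_epochset


class TestSplitData:
    def test_100_single_epoch_subjects_split_70_12_18(self):
        eps = make_epochset(["HC"] * 60 + ["AD"] * 25 + ["MCI"] * 15, seed=0)
        tr, va, te = split_data(eps, SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (70, 12, 18)

    def test_subject_level_keeps_subjects_whole(self):
        labels = ["HC"] * 12 + ["AD"] * 8
        sids = [f"S{i // 2}" for i in range(20)]  # two epochs per subject
        eps = make_epochset(labels, subject_ids=sids, seed=1)
        tr, va, te = split_data(eps, SplitSpec(seed=2))
        sets = [set(tr.subject_ids), set(va.subject_ids), set(te.subject_ids)]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        # every subject's two epochs land together
        for part in (tr, va, te):
            for sid in set(part.subject_ids):
                assert np.sum(part.subject_ids == sid) == 2

    def test_partition_is_exact(self):
        eps = make_epochset(["HC"] * 30 + ["MCI"] * 10, seed=3)
        tr, va, te = split_indices(eps, SplitSpec(seed=5))
        combined = np.concatenate([tr, va, te])
        assert sorted(combined) == list(range(len(eps)))

    def test_fixed_test_composition_honored(self):
        labels = ["HC"] * 102 + ["MCI"] * 7 + ["AD"] * 59
        eps = make_epochset(labels, n_channels=1, duration_s=0.25,
                            fs_hz=64.0, seed=4)
        spec = SplitSpec(fixed_test_composition=STUDY_TEST_COMPOSITION, seed=6)
        _, _, te = split_data(eps, spec)
        counts = te.class_counts()
        assert counts[Diagnosis.MCI] == 3
        assert counts[Diagnosis.HC] == 30
        assert counts[Diagnosis.AD] == 17

    def test_infeasible_composition_names_class(self):
        eps = make_epochset(["HC"] * 5 + ["MCI"] * 2, seed=7)
        with pytest.raises(ValueError, match="MCI"):
            split_data(eps, SplitSpec(
                fixed_test_composition={Diagnosis.MCI: 5}, seed=0))

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(ratios=(0.5, 0.5, 0.5))


class TestMakeTask:
    def test_pairwise_drops_third_class(self):
        labels = [Diagnosis.HC, Diagnosis.MCI, Diagnosis.AD, Diagnosis.HC]
        kept, y = make_task(labels, Task.MCI_VS_HC)
        assert kept.tolist() == [0, 1, 3]
        assert y == ["HC", "MCI", "HC"]

    def test_admci_pools_positive_class(self):
        labels = [Diagnosis.HC, Diagnosis.MCI, Diagnosis.AD]
        kept, y = make_task(labels, Task.ADMCI_VS_HC)
        assert kept.tolist() == [0, 1, 2]
        assert y == ["HC", "ADMCI", "ADMCI"]

    def test_three_class_is_identity(self):
        labels = [Diagnosis.AD, Diagnosis.HC, Diagnosis.MCI]
        kept, y = make_task(labels, Task.THREE_CLASS)
        assert kept.tolist() == [0, 1, 2]
        assert y == ["AD", "HC", "MCI"]

    def test_absent_class_raises(self):
        with pytest.raises(ValueError, match="MCI"):
            make_task([Diagnosis.HC, Diagnosis.AD], Task.MCI_VS_HC)


def blobs(n_per_class=20, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.standard_normal((n_per_class, 2)),
                        rng.standard_normal((n_per_class, 2)) + sep])
    labels = [Diagnosis.HC] * n_per_class + [Diagnosis.AD] * n_per_class
    return FeatureMatrix(X=X, feature_names=["f1", "f2"], labels=labels,
                         subject_ids=[f"S{i}" for i in range(2 * n_per_class)])


class TestClassifier:
    def test_separable_blobs_perfect_training_accuracy(self):
        fm = blobs()
        clf = train_classifier(fm)
        assert (clf.predict(fm.X) == [l.value for l in fm.labels]).all()

    def test_deterministic_predictions(self):
        fm = blobs(seed=1)
        probe = blobs(seed=2)
        a = train_classifier(fm).predict(probe.X)
        b = train_classifier(fm).predict(probe.X)
        assert (a == b).all()

    def test_single_class_raises(self):
        fm = blobs()
        with pytest.raises(ValueError, match="single class"):
            train_classifier(fm, y=["HC"] * len(fm))


class _Stub:
    def __init__(self, preds):
        self.preds = list(preds)

    def predict(self, X):
        return np.asarray(self.preds[: len(X)])


class TestEvaluate:
    def test_perfect_predictions(self):
        fm = blobs(n_per_class=3)
        y = [l.value for l in fm.labels]
        res = evaluate(_Stub(y), fm, y=y)
        assert res.accuracy == 1.0 and res.f1 == 1.0

    def test_known_confusion_matrix(self):
        # TP=3, FN=1, FP=1, TN=5 -> acc 0.8, macro F1 (0.75 + 0.8333)/2
        y = ["pos"] * 4 + ["neg"] * 6
        pred = ["pos"] * 3 + ["neg"] + ["pos"] + ["neg"] * 5
        fm = blobs(n_per_class=5)
        res = evaluate(_Stub(pred), fm, y=y)
        assert res.accuracy == pytest.approx(0.8)
        assert res.f1 == pytest.approx((0.75 + 5 / 6) / 2, abs=1e-9)
        assert np.trace(res.confusion) / res.confusion.sum() == res.accuracy

    def test_degenerate_predictor_macro_f1_below_accuracy(self):
        y = ["a"] * 5 + ["b"] * 5
        res = evaluate(_Stub(["a"] * 10), blobs(n_per_class=5), y=y)
        assert res.f1 < res.accuracy

    def test_empty_test_set_raises(self):
        fm = blobs(n_per_class=2).select(np.asarray([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            evaluate(_Stub([]), fm)


@pytest.fixture(scope="module")
def mini_experiment(small_cohort):
    cfg = ExperimentConfig(
        tasks=(Task.MCI_VS_HC, Task.ADMCI_VS_HC),
        methods=(AugmentMethod.NONE, AugmentMethod.NOISE),
        epoch_durations_s=(10.0,), n_trials=2, master_seed=9)
    return cfg, run_experiment(small_cohort, cfg)


class TestRunExperiment:
    def test_cell_count(self, mini_experiment):
        cfg, (res, trials) = mini_experiment
        assert len(res.table) == 2 * 2 * 1
        assert len(trials) == 2 * 2 * 1 * cfg.n_trials

    def test_metrics_in_range(self, mini_experiment):
        _, (res, trials) = mini_experiment
        ok = trials[trials["error"] == ""]
        assert ok["accuracy"].between(0, 1).all()
        assert ok["f1"].between(0, 1).all()

    def test_augmentation_never_touches_val_or_test(self, mini_experiment):
        # the val/test hash is constant across methods within a trial
        _, (_, trials) = mini_experiment
        for (_, _), grp in trials.groupby(["duration_s", "trial"]):
            assert grp["val_hash"].nunique() == 1
            assert grp["test_hash"].nunique() == 1

    def test_single_trial_mean_equals_trial(self, small_cohort):
        cfg = ExperimentConfig(tasks=(Task.ADMCI_VS_HC,),
                               methods=(AugmentMethod.NONE,),
                               epoch_durations_s=(10.0,), n_trials=1,
                               master_seed=3)
        res, trials = run_experiment(small_cohort, cfg)
        assert res.table["mean_accuracy"].iloc[0] == trials["accuracy"].iloc[0]

    def test_deterministic_under_master_seed(self, small_cohort,
                                             mini_experiment):
        cfg, (res, _) = mini_experiment
        res2, _ = run_experiment(small_cohort, cfg)
        assert res.table.equals(res2.table)
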