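"""Experimental protocol: splits, diagnostic tasks, SVM, repeated trials.

Reproduces the study design around the feature and augmentation stages:
subject-level 70:12:18 train/validation/test splits (optionally with a
fixed per-class test composition), four diagnostic tasks (three-class,
MCI vs HC, AD vs MCI, AD+MCI vs HC), augmentation of the training set
only, an RBF-kernel SVM over the 152 features, and aggregation of
accuracy and macro F1 over repeated random re-splits into a
tasks x methods x durations results table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .augment import AugmentMethod, NoiseAugmentConfig, balance_training_set
from .features import DEFAULT_BANDS, WelchConfig, extract_features
from .types import Diagnosis, EpochSet, FeatureMatrix
from .vae import VAEConfig, train_vae

__all__ = [
    "Task",
    "SplitSpec",
    "SVMSettings",
    "ExperimentConfig",
    "TrialResult",
    "ResultsTable",
    "split_data",
    "make_task",
    "train_classifier",
    "evaluate",
    "run_experiment",
]


class Task(str, Enum):
    THREE_CLASS = "MCI_vs_AD_vs_HC"
    MCI_VS_HC = "MCI_vs_HC"
    AD_VS_MCI = "AD_vs_MCI"
    ADMCI_VS_HC = "ADMCI_vs_HC"


class SplitLevel(str, Enum):
    SUBJECT = "subject"
    EPOCH = "epoch"


#: The study's fixed per-class test composition (subjects).
STUDY_TEST_COMPOSITION = {Diagnosis.MCI: 3, Diagnosis.HC: 30, Diagnosis.AD: 17}


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test split specification.

    Ratios default to 70:12:18. Subject-level splitting keeps all epochs
    of one subject in one set (no leakage); splits are stratified by
    diagnosis with largest-remainder rounding per class.
    ``fixed_test_composition`` forces per-class subject counts in the test
    set (e.g. the study's MCI:3, HC:30, AD:17).
    """

    ratios: tuple = (0.70, 0.12, 0.18)
    level: SplitLevel = SplitLevel.SUBJECT
    fixed_test_composition: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or min(self.ratios) <= 0:
            raise ValueError("ratios must be three positive numbers")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


def _largest_remainder(n: int, ratios) -> list:
    """Integer apportionment of n by ratios; ties go to the earlier set."""
    raw = np.asarray(ratios, dtype=float) * n
    base = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - base), kind="stable")[: n - base.sum()]:
        base[i] += 1
    return base.tolist()


def _split_units(units: np.ndarray, rng: np.random.Generator, ratios,
                 n_test_fixed: int | None):
    units = rng.permutation(units)
    if n_test_fixed is None:
        n_tr, n_va, n_te = _largest_remainder(len(units), ratios)
    else:
        n_te = n_test_fixed
        rest = len(units) - n_te
        tv = np.asarray(ratios[:2], dtype=float)
        n_tr, n_va = _largest_remainder(rest, tv / tv.sum())
    return (units[:n_tr], units[n_tr : n_tr + n_va],
            units[n_tr + n_va : n_tr + n_va + n_te])


def split_indices(eps: EpochSet, spec: SplitSpec):
    """Epoch-index arrays (train, val, test) under ``spec``.

    Stratified by diagnosis; deterministic under ``spec.seed``.
    """
    if len(eps) == 0:
        raise ValueError("cannot split an empty EpochSet")
    rng = np.random.default_rng(spec.seed)
    comp = None
    if spec.fixed_test_composition is not None:
        comp = {Diagnosis.coerce(k): v
                for k, v in spec.fixed_test_composition.items()}
    idx_sets: list = [[], [], []]
    for lab in sorted({l for l in eps.labels}, key=lambda l: l.value):
        mask = eps.labels == lab
        if spec.level is SplitLevel.SUBJECT:
            subjects = pd.unique(eps.subject_ids[mask])
            n_fixed = comp.get(lab, 0) if comp is not None else None
            if n_fixed is not None and n_fixed > len(subjects):
                raise ValueError(
                    f"test composition requires {n_fixed} {lab.value} subjects "
                    f"but only {len(subjects)} are available")
            groups = _split_units(np.asarray(subjects, dtype=object), rng,
                                  spec.ratios, n_fixed)
            sid_to_idx: dict = {}
            for i in np.where(mask)[0]:
                sid_to_idx.setdefault(eps.subject_ids[i], []).append(i)
            for dest, subj_group in zip(idx_sets, groups):
                for sid in subj_group:
                    dest.extend(sid_to_idx[sid])
        else:
            lab_idx = np.where(mask)[0]
            n_fixed = comp.get(lab, 0) if comp is not None else None
            if n_fixed is not None and n_fixed > len(lab_idx):
                raise ValueError(
                    f"test composition requires {n_fixed} {lab.value} epochs "
                    f"but only {len(lab_idx)} are available")
            groups = _split_units(lab_idx, rng, spec.ratios, n_fixed)
            for dest, g in zip(idx_sets, groups):
                dest.extend(int(i) for i in g)
    return tuple(np.sort(np.asarray(s, dtype=int)) for s in idx_sets)


def split_data(eps: EpochSet, spec: SplitSpec):
    """Partition an EpochSet into (train, val, test)."""
    tr, va, te = split_indices(eps, spec)
    return eps.select(tr), eps.select(va), eps.select(te)


#: Per-task label mapping: None drops the example.
_TASK_MAPS = {
    Task.THREE_CLASS: {Diagnosis.HC: "HC", Diagnosis.MCI: "MCI",
                       Diagnosis.AD: "AD"},
    Task.MCI_VS_HC: {Diagnosis.HC: "HC", Diagnosis.MCI: "MCI"},
    Task.AD_VS_MCI: {Diagnosis.AD: "AD", Diagnosis.MCI: "MCI"},
    Task.ADMCI_VS_HC: {Diagnosis.HC: "HC", Diagnosis.MCI: "ADMCI",
                       Diagnosis.AD: "ADMCI"},
}


def make_task(labels, task: Task):
    """(kept indices, task labels) for one diagnostic task.

    Pairwise tasks drop the third class; AD+MCI vs HC pools AD and MCI
    into one positive class. Raises if a task class has no examples.
    """
    task = Task(task)
    mapping = _TASK_MAPS[task]
    labels = [Diagnosis.coerce(l) for l in labels]
    if not labels:
        raise ValueError("empty label list")
    kept = [i for i, l in enumerate(labels) if l in mapping]
    task_labels = [mapping[labels[i]] for i in kept]
    present = set(task_labels)
    missing = set(mapping.values()) - present
    if missing:
        raise ValueError(
            f"task {task.value}: class(es) {sorted(missing)} absent from labels")
    return np.asarray(kept, dtype=int), task_labels


@dataclass(frozen=True)
class SVMSettings:
    """Kernelized max-margin classifier settings (RBF, C=1, width 1/(d*var))."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: object = "scale"


def train_classifier(train_features: FeatureMatrix, svm: SVMSettings = SVMSettings(),
                     y=None):
    """Column-standardize by train statistics and fit the SVM.

    ``y`` overrides the feature matrix's diagnosis labels with task labels.
    """
    if y is None:
        y = [l.value for l in train_features.labels]
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    clf = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=svm.kernel, C=svm.C, gamma=svm.gamma)),
    ])
    clf.fit(train_features.X, y)
    return clf


@dataclass
class TrialResult:
    """One (task, method, duration, trial) evaluation."""

    task: str
    method: str
    duration_s: float
    trial_index: int
    accuracy: float
    f1: float  # macro-averaged
    confusion: np.ndarray
    classes: list
    f1_per_class: dict

    def __post_init__(self) -> None:
        total = self.confusion.sum()
        if total and abs(self.accuracy - np.trace(self.confusion) / total) > 1e-12:
            raise ValueError("accuracy inconsistent with confusion matrix")


def evaluate(classifier, test_features: FeatureMatrix, y=None, *,
             task="", method="", duration_s=float("nan"),
             trial_index=-1) -> TrialResult:
    """Accuracy, macro F1 and confusion matrix (rows true, columns predicted)."""
    if len(test_features) == 0:
        raise ValueError("empty test set")
    if y is None:
        y = [l.value for l in test_features.labels]
    pred = classifier.predict(test_features.X)
    classes = sorted(set(y) | set(pred))
    cm = confusion_matrix(y, pred, labels=classes)
    per_class = f1_score(y, pred, labels=classes, average=None, zero_division=0)
    return TrialResult(
        task=str(task), method=str(method), duration_s=float(duration_s),
        trial_index=int(trial_index),
        accuracy=float(accuracy_score(y, pred)),
        f1=float(f1_score(y, pred, labels=classes, average="macro",
                          zero_division=0)),
        confusion=cm, classes=classes,
        f1_per_class={c: float(v) for c, v in zip(classes, per_class)})


@dataclass(frozen=True)
class ExperimentConfig:
    """Full protocol configuration (tasks x methods x durations x trials)."""

    tasks: tuple = (Task.THREE_CLASS, Task.MCI_VS_HC, Task.AD_VS_MCI,
                    Task.ADMCI_VS_HC)
    methods: tuple = (AugmentMethod.NONE, AugmentMethod.NOISE,
                      AugmentMethod.VAE, AugmentMethod.HYBRID)
    epoch_durations_s: tuple = (5.0, 10.0, 15.0)
    n_trials: int = 50
    master_seed: int = 0
    svm: SVMSettings = SVMSettings()
    split: SplitSpec = SplitSpec()
    noise_cfg: NoiseAugmentConfig = NoiseAugmentConfig()
    vae_cfg: VAEConfig = VAEConfig()
    welch_cfg: WelchConfig = WelchConfig()

    def __post_init__(self) -> None:
        if not self.tasks or not self.methods or not self.epoch_durations_s:
            raise ValueError("tasks, methods and durations must be non-empty")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        object.__setattr__(self, "tasks", tuple(Task(t) for t in self.tasks))
        object.__setattr__(self, "methods",
                           tuple(AugmentMethod(m) for m in self.methods))


@dataclass
class ResultsTable:
    """Mean accuracy/F1 per (task x method x duration) over trials."""

    table: pd.DataFrame
    n_trials: int


def _hash_epochs(eps: EpochSet) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(eps.epochs).tobytes())
    h.update("|".join(l.value for l in eps.labels).encode())
    h.update("|".join(eps.subject_ids).encode())
    return h.hexdigest()


def _trial_seeds(master_seed: int, d_idx: int, trial: int, k: int):
    state = np.random.SeedSequence([master_seed, d_idx, trial]).generate_state(k)
    return [int(s % (2**31)) for s in state]


def run_experiment(data, cfg: ExperimentConfig):
    """Run the full protocol and aggregate results.

    ``data`` is either a list of EEGRecording (preprocessed here per epoch
    duration with default settings) or a mapping duration -> EpochSet.
    Per (duration, trial): re-split with a trial-derived seed, augment the
    training set only (one shared VAE per trial when needed), extract
    features, train and evaluate each task. Features of original epochs
    are computed once per duration and reused across trials and methods.

    Returns (ResultsTable, trials DataFrame). A failing cell is recorded
    with NaN metrics and an ``error`` note; other cells continue. The val
    and test content hashes are logged per trial so augmentation can be
    audited never to touch them.
    """
    from .preprocess import PreprocessConfig, epochs_from_cohort

    if isinstance(data, dict):
        eps_by_dur = {float(d): e for d, e in data.items()}
    else:
        eps_by_dur = {
            float(d): epochs_from_cohort(
                data, PreprocessConfig(epoch_duration_s=float(d)))
            for d in cfg.epoch_durations_s}

    rows = []
    needs_vae = any(m in (AugmentMethod.VAE, AugmentMethod.HYBRID)
                    for m in cfg.methods)
    for d_idx, duration in enumerate(sorted(float(d)
                                            for d in cfg.epoch_durations_s)):
        eps = eps_by_dur[duration]
        feats_all = extract_features(eps, DEFAULT_BANDS, cfg.welch_cfg)
        for trial in range(cfg.n_trials):
            s_split, s_vae, s_aug = _trial_seeds(cfg.master_seed, d_idx, trial, 3)
            idx_tr, idx_va, idx_te = split_indices(
                eps, replace(cfg.split, seed=s_split))
            train_eps = eps.select(idx_tr)
            val_eps, test_eps = eps.select(idx_va), eps.select(idx_te)
            val_hash, test_hash = _hash_epochs(val_eps), _hash_epochs(test_eps)
            feats_test = feats_all.select(idx_te)
            feats_train_orig = feats_all.select(idx_tr)

            vmodel = None
            if needs_vae:
                vmodel = train_vae(train_eps, replace(cfg.vae_cfg, seed=s_vae))

            for method in cfg.methods:
                try:
                    aug = balance_training_set(
                        train_eps, method, cfg.noise_cfg, vmodel, seed=s_aug)
                    if len(aug) > len(train_eps):
                        artificial = aug.select(
                            np.arange(len(train_eps), len(aug)))
                        feats_art = extract_features(
                            artificial, DEFAULT_BANDS, cfg.welch_cfg)
                        feats_train = FeatureMatrix.concatenate(
                            [feats_train_orig, feats_art])
                    else:
                        feats_train = feats_train_orig
                except Exception as exc:  # augmentation failed for this cell
                    for task in cfg.tasks:
                        rows.append(_failed_row(task, method, duration, trial,
                                                val_hash, test_hash, exc))
                    continue
                for task in cfg.tasks:
                    try:
                        kept_tr, y_tr = make_task(feats_train.labels, task)
                        kept_te, y_te = make_task(feats_test.labels, task)
                        clf = train_classifier(feats_train.select(kept_tr),
                                               cfg.svm, y=y_tr)
                        res = evaluate(clf, feats_test.select(kept_te), y=y_te,
                                       task=task.value, method=method.value,
                                       duration_s=duration, trial_index=trial)
                        rows.append(dict(
                            task=task.value, method=method.value,
                            duration_s=duration, trial=trial,
                            accuracy=res.accuracy, f1=res.f1,
                            f1_per_class="|".join(
                                f"{c}:{v:.6f}"
                                for c, v in res.f1_per_class.items()),
                            n_test=int(res.confusion.sum()),
                            val_hash=val_hash, test_hash=test_hash, error=""))
                    except Exception as exc:
                        rows.append(_failed_row(task, method, duration, trial,
                                                val_hash, test_hash, exc))

    trials = pd.DataFrame(rows)
    ok = trials[trials["error"] == ""]
    table = (ok.groupby(["task", "method", "duration_s"], as_index=False)
               .agg(mean_accuracy=("accuracy", "mean"),
                    mean_f1=("f1", "mean"),
                    n_trials=("trial", "count")))
    # keep the requested ordering
    table["task"] = pd.Categorical(table["task"],
                                   [t.value for t in cfg.tasks], ordered=True)
    table["method"] = pd.Categorical(table["method"],
                                     [m.value for m in cfg.methods], ordered=True)
    table = table.sort_values(["duration_s", "task", "method"],
                              ignore_index=True)
    table["task"] = table["task"].astype(str)
    table["method"] = table["method"].astype(str)
    return ResultsTable(table=table, n_trials=cfg.n_trials), trials


def _failed_row(task, method, duration, trial, val_hash, test_hash, exc):
    return dict(task=Task(task).value, method=AugmentMethod(method).value,
                duration_s=duration, trial=trial, accuracy=float("nan"),
                f1=float("nan"), f1_per_class="", n_test=0,
                val_hash=val_hash, test_hash=test_hash, error=str(exc))
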