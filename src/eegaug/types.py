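"""Core in-memory containers shared by every pipeline stage.

The unit of classification throughout is the *epoch*: a fixed-duration
window of a multichannel scalp recording. Diagnostic labels follow the
three-class AD / MCI / HC scheme used in clinical EEG studies of
Alzheimer's disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

#: The 19 scalp electrodes of the international 10-20 placement system,
#: in canonical order. This order defines feature-vector layout.
CHANNELS_1020 = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


class Diagnosis(Enum):
    """Diagnostic class: healthy control, mild cognitive impairment, Alzheimer's.

    A plain (non-str) Enum: NumPy object arrays then compare elementwise by
    identity, so masks like ``labels == Diagnosis.MCI`` behave correctly.
    """

    HC = "HC"
    MCI = "MCI"
    AD = "AD"

    @classmethod
    def coerce(cls, value: "Diagnosis | str") -> "Diagnosis":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(f"unknown diagnosis label: {value!r}") from None


#: Fixed label order used for one-hot encodings and confusion matrices.
LABEL_ORDER = (Diagnosis.HC, Diagnosis.MCI, Diagnosis.AD)


@dataclass
class EEGRecording:
    """One subject's labeled multichannel EEG signal.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    label : Diagnosis
        Diagnostic class of the subject.
    fs_hz : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Electrode labels, one per data row.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    subject_id: str
    label: Diagnosis
    fs_hz: float
    channel_names: tuple
    data: np.ndarray

    def __post_init__(self) -> None:
        self.label = Diagnosis.coerce(self.label)
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class EpochSet:
    """Fixed-duration labeled epochs — the unit of augmentation and classification.

    ``epochs`` has shape (n, n_channels, n_samples) in microvolts; ``labels``
    and ``subject_ids`` are parallel arrays of length n.
    """

    epochs: np.ndarray
    fs_hz: float
    duration_s: float
    labels: np.ndarray  # array of Diagnosis
    subject_ids: np.ndarray  # array of str
    channel_names: tuple

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(
            [Diagnosis.coerce(l) for l in np.asarray(self.labels).ravel()],
            dtype=object,
        )
        self.subject_ids = np.asarray(
            [str(s) for s in np.asarray(self.subject_ids).ravel()], dtype=object
        )
        self.channel_names = tuple(self.channel_names)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n x channels x samples)")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids length must equal number of epochs")
        if self.epochs.shape[1] != len(self.channel_names):
            raise ValueError("channel dimension does not match channel_names")
        expected = int(round(self.duration_s * self.fs_hz))
        if n > 0 and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != duration*fs = {expected}"
            )
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain non-finite values")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def select(self, index) -> "EpochSet":
        """Subset by boolean mask or integer index array (copying)."""
        index = np.asarray(index)
        return EpochSet(
            epochs=self.epochs[index].copy(),
            fs_hz=self.fs_hz,
            duration_s=self.duration_s,
            labels=self.labels[index].copy(),
            subject_ids=self.subject_ids[index].copy(),
            channel_names=self.channel_names,
        )

    def class_counts(self) -> dict:
        out: dict = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    @staticmethod
    def concatenate(sets: "list[EpochSet]") -> "EpochSet":
        sets = [s for s in sets if len(s) > 0]
        if not sets:
            raise ValueError("cannot concatenate zero non-empty EpochSets")
        first = sets[0]
        for s in sets[1:]:
            if s.fs_hz != first.fs_hz or s.channel_names != first.channel_names \
                    or s.n_samples != first.n_samples:
                raise ValueError("incompatible EpochSets")
        return EpochSet(
            epochs=np.concatenate([s.epochs for s in sets], axis=0),
            fs_hz=first.fs_hz,
            duration_s=first.duration_s,
            labels=np.concatenate([s.labels for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            channel_names=first.channel_names,
        )


def empty_epochset(template: EpochSet) -> EpochSet:
    """An EpochSet with zero epochs sharing ``template``'s geometry."""
    return EpochSet(
        epochs=np.empty((0, template.n_channels, template.n_samples)),
        fs_hz=template.fs_hz,
        duration_s=template.duration_s,
        labels=np.empty(0, dtype=object),
        subject_ids=np.empty(0, dtype=object),
        channel_names=template.channel_names,
    )


@dataclass
class FeatureMatrix:
    """Per-epoch feature table: n rows by d named columns, with labels and subject ids."""

    X: np.ndarray
    feature_names: list
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must equal number of columns")
        n = self.X.shape[0]
        self.labels = np.asarray(list(self.labels), dtype=object)
        self.subject_ids = np.asarray([str(s) for s in self.subject_ids], dtype=object)
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids length must equal number of rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return self.X.shape[0]

    def select(self, index) -> "FeatureMatrix":
        index = np.asarray(index)
        return FeatureMatrix(
            X=self.X[index].copy(),
            feature_names=list(self.feature_names),
            labels=self.labels[index].copy(),
            subject_ids=self.subject_ids[index].copy(),
        )

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["label"] = [l.value for l in self.labels]
        df["subject_id"] = list(self.subject_ids)
        return df

    @staticmethod
    def concatenate(mats: "list[FeatureMatrix]") -> "FeatureMatrix":
        mats = [m for m in mats if len(m) > 0]
        if not mats:
            raise ValueError("cannot concatenate zero non-empty FeatureMatrices")
        names = mats[0].feature_names
        for m in mats[1:]:
            if list(m.feature_names) != list(names):
                raise ValueError("feature name mismatch")
        return FeatureMatrix(
            X=np.concatenate([m.X for m in mats], axis=0),
            feature_names=list(names),
            labels=np.concatenate([m.labels for m in mats]),
            subject_ids=np.concatenate([m.subject_ids for m in mats]),
        )
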