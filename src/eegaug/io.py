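"""Standard-format I/O: EDF recordings, manifests, epoch containers, results.

Recordings travel as EDF (the clinical interchange format; 16-bit, so
round trips quantize), indexed by a CSV manifest of
``subject_id,label,file``. Between pipeline stages epochs are stored in
a lossless NumPy archive. Results are written as fixed-precision CSV so
reruns are byte-identical.

EDF writing is implemented here directly (ASCII header plus int16 data
records, one-second records); reading uses :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import warnings
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CHANNELS_1020, Diagnosis, EEGRecording, EpochSet

__all__ = [
    "write_edf",
    "read_recording",
    "write_manifest",
    "read_manifest",
    "save_epochs",
    "load_epochs",
    "write_results",
]

_EPOCHS_SCHEMA = "eegaug-epochs-v1"


# ---------------------------------------------------------------------------
# EDF

def _pad(text: str, width: int) -> bytes:
    b = str(text).encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as EDF (16-bit, one-second data records).

    Requires an integer sampling rate; a trailing partial second is
    truncated. Physical range is set per channel to the data extremes, so
    quantization error is at most range/2^16.
    """
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_rec * fs]
    ns = rec.n_channels

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(f"{rec.subject_id} {rec.label.value}", 80),
        _pad("Startdate 01-JAN-2000 synthetic", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        [_pad(f"EEG {ch}", 16) for ch in rec.channel_names],
        [_pad("AgAgCl electrode", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{v:.2f}"[:8], 8) for v in pmin],
        [_pad(f"{v:.2f}"[:8], 8) for v in pmax],
        [_pad(str(dmin), 8)] * ns,
        [_pad(str(dmax), 8)] * ns,
        [_pad("none", 80)] * ns,
        [_pad(str(fs), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # data records: channel-sequential within each one-second record
        fh.write(np.ascontiguousarray(
            digital.reshape(ns, n_rec, fs).transpose(1, 0, 2)).tobytes())
    # re-quantize check is the caller's concern; the format guarantees 16 bits


def read_recording(path, subject_id: str, label,
                   expected_channels=CHANNELS_1020) -> EEGRecording:
    """Read an EDF file and attach manifest metadata.

    Channels are returned in the canonical order of ``expected_channels``
    when all its names are present (reordering with a warning if stored
    order differs); otherwise the stored order is kept with a warning.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    if expected_channels is not None:
        expected = list(expected_channels)
        if sorted(names) == sorted(expected):
            if names != expected:
                warnings.warn(
                    f"{path.name}: channels stored in non-canonical order; "
                    "reordering by name", stacklevel=2)
                order = [names.index(ch) for ch in expected]
                data = data[order]
                names = expected
        else:
            warnings.warn(
                f"{path.name}: channel set differs from the expected "
                f"{len(expected)}-channel montage; keeping stored channels",
                stacklevel=2)
    return EEGRecording(subject_id=subject_id, label=Diagnosis.coerce(label),
                        fs_hz=float(raw.info["sfreq"]),
                        channel_names=tuple(names), data=data)


# ---------------------------------------------------------------------------
# Manifest

def write_manifest(rows, path) -> None:
    """rows: iterable of (subject_id, label, file)."""
    df = pd.DataFrame(rows, columns=["subject_id", "label", "file"])
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in manifest")
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "label", "file"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in manifest")
    df["label"] = [Diagnosis.coerce(l).value for l in df["label"]]
    for f in df["file"]:
        if not (path.parent / f).exists():
            raise FileNotFoundError(f"manifest references missing file: {f}")
    return df


def read_cohort(manifest_path) -> list:
    """Load every recording listed in a manifest."""
    path = Path(manifest_path)
    df = read_manifest(path)
    return [read_recording(path.parent / row.file, row.subject_id, row.label)
            for row in df.itertuples()]


# ---------------------------------------------------------------------------
# Epoch container (lossless)

def save_epochs(eps: EpochSet, path) -> None:
    np.savez(
        path,
        schema=np.str_(_EPOCHS_SCHEMA),
        epochs=eps.epochs,
        fs_hz=np.float64(eps.fs_hz),
        duration_s=np.float64(eps.duration_s),
        labels=np.asarray([l.value for l in eps.labels], dtype="U8"),
        subject_ids=np.asarray(list(eps.subject_ids), dtype="U64"),
        channel_names=np.asarray(list(eps.channel_names), dtype="U16"),
    )


def load_epochs(path) -> EpochSet:
    try:
        with np.load(path, allow_pickle=False) as data:
            if "schema" not in data or str(data["schema"]) != _EPOCHS_SCHEMA:
                raise ValueError(
                    f"not a {_EPOCHS_SCHEMA} container: {path}")
            return EpochSet(
                epochs=data["epochs"],
                fs_hz=float(data["fs_hz"]),
                duration_s=float(data["duration_s"]),
                labels=data["labels"],
                subject_ids=data["subject_ids"],
                channel_names=tuple(data["channel_names"]),
            )
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as exc:
        raise ValueError(f"cannot load epoch container {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Results

def write_results(results_table, trials, out_dir) -> dict:
    """Write ``results_table.csv`` and ``trials.csv`` (floats at 4 decimals).

    ``results_table`` is a ResultsTable or its DataFrame; ``trials`` the
    per-trial DataFrame. Raises on empty results. Returns the paths.
    """
    table = getattr(results_table, "table", results_table)
    trials = pd.DataFrame(trials)
    if len(table) == 0 or len(trials) == 0:
        raise ValueError("refusing to write empty results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"results": out_dir / "results_table.csv",
             "trials": out_dir / "trials.csv"}
    table.to_csv(paths["results"], index=False, float_format="%.4f")
    trials.to_csv(paths["trials"], index=False, float_format="%.4f")
    return paths
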