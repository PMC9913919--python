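"""Spectral and temporal feature extraction.

Per epoch and channel: the average Welch power spectral density inside
the five canonical clinical bands (delta, theta, alpha, beta, gamma)
plus three time-domain statistics (mean, variance, zero-crossing rate).
With 19 channels this yields the 152-dimensional feature vector
(95 spectral + 57 statistical) used by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .types import EpochSet, FeatureMatrix

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "WelchConfig",
    "welch_psd",
    "band_mean_psd",
    "band_integrated_psd",
    "zcr",
    "extract_features",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi); ``closed_hi`` closes the upper edge."""

    name: str
    lo_hz: float
    hi_hz: float
    closed_hi: bool = False

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: lo must be < hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        if self.closed_hi:
            return (freqs >= self.lo_hz) & (freqs <= self.hi_hz)
        return (freqs >= self.lo_hz) & (freqs < self.hi_hz)


#: Canonical clinical band edges partitioning [1, 50] Hz exactly: half-open
#: [lo, hi) except gamma, closed at 50 Hz.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0, closed_hi=True),
)


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings: 2-s Hann segments at 50% overlap by default
    (0.5 Hz resolution, so the delta band holds several bins at fs 128)."""

    segment_s: float = 2.0
    overlap_fraction: float = 0.5
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.segment_s <= 0:
            raise ValueError("segment_s must be positive")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")

    def nperseg(self, fs_hz: float) -> int:
        n = int(round(self.segment_s * fs_hz))
        if n < 2:
            raise ValueError("segment_s * fs must be at least 2 samples")
        return n

    def noverlap(self, fs_hz: float) -> int:
        return int(round(self.nperseg(fs_hz) * self.overlap_fraction))


def welch_psd(x: np.ndarray, fs_hz: float, cfg: WelchConfig = WelchConfig()):
    """Welch PSD estimate (one-sided, power/Hz) along the last axis.

    Accepts a vector or any array whose last axis is time. The signal must
    be at least one segment long.
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = cfg.nperseg(fs_hz)
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than one Welch segment ({nperseg})"
        )
    freqs, psd = sp_signal.welch(
        x, fs=fs_hz, window=cfg.window, nperseg=nperseg,
        noverlap=cfg.noverlap(fs_hz), detrend="constant", axis=-1)
    return freqs, psd


def band_mean_psd(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> float:
    """Arithmetic mean of PSD values at grid frequencies inside the band."""
    mask = band.mask(np.asarray(freqs))
    if not mask.any():
        raise ValueError(
            f"no frequency grid point falls inside band {band.name} "
            f"[{band.lo_hz}, {band.hi_hz}]"
        )
    return np.mean(np.asarray(psd)[..., mask], axis=-1)


def band_integrated_psd(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition):
    """Rectangle-rule band power: sum of PSD * df over grid points in the band.

    Because the default bands partition [1, 50] over the grid with no shared
    points, these integrals sum exactly to the integral over [1, 50].
    """
    freqs = np.asarray(freqs)
    mask = band.mask(freqs)
    if not mask.any():
        raise ValueError(f"no frequency grid point falls inside band {band.name}")
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    return np.sum(np.asarray(psd)[..., mask], axis=-1) * df


def zcr(x: np.ndarray) -> np.ndarray:
    """Zero-crossing rate along the last axis, in [0, 1].

    Counts adjacent sample pairs with strictly opposite sign, divided by
    len-1. Zero samples inherit the sign of the previous nonzero sample
    (leading zeros carry no sign and never produce a crossing).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("zcr requires at least 2 samples")
    s = np.sign(x)
    # forward-fill zero signs with the previous nonzero sign; leading zeros
    # resolve to index 0, which is itself zero, so they stay signless
    if (s == 0).any():
        idx = np.where(s == 0, 0, np.arange(x.shape[-1]))
        idx = np.maximum.accumulate(idx, axis=-1)
        s = np.take_along_axis(s, idx, axis=-1)
    crossings = np.sum(s[..., 1:] * s[..., :-1] < 0, axis=-1)
    return crossings / (x.shape[-1] - 1)


def extract_features(eps: EpochSet, bands=DEFAULT_BANDS,
                     cfg: WelchConfig = WelchConfig()) -> FeatureMatrix:
    """Compute the full per-epoch feature matrix.

    Row layout: for each channel the band-average PSD values in band order,
    then for each channel (mean, variance, ZCR). Feature names are
    ``<channel>_<band>_psd`` and ``<channel>_{mean|var|zcr}``. Variance is
    the population variance (divide by N).
    """
    if len(eps) == 0:
        raise ValueError("cannot extract features from an empty EpochSet")
    if not np.all(np.isfinite(eps.epochs)):
        bad = np.where(~np.isfinite(eps.epochs).all(axis=(1, 2)))[0]
        raise ValueError(f"non-finite values in epoch(s) {bad.tolist()}")
    freqs, psd = welch_psd(eps.epochs, eps.fs_hz, cfg)  # (n, C, F)
    n, n_ch = psd.shape[0], psd.shape[1]
    spectral = np.empty((n, n_ch, len(bands)))
    for j, band in enumerate(bands):
        spectral[:, :, j] = band_mean_psd(freqs, psd, band)
    stats = np.stack(
        [eps.epochs.mean(axis=-1), eps.epochs.var(axis=-1), zcr(eps.epochs)],
        axis=-1)  # (n, C, 3)
    X = np.concatenate(
        [spectral.reshape(n, -1), stats.reshape(n, -1)], axis=1)
    names = [f"{ch}_{band.name}_psd" for ch in eps.channel_names for band in bands]
    names += [f"{ch}_{stat}" for ch in eps.channel_names
              for stat in ("mean", "var", "zcr")]
    return FeatureMatrix(X=X, feature_names=names,
                         labels=eps.labels.copy(), subject_ids=eps.subject_ids.copy())
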