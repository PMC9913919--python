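"""Synthetic EEG cohort generator with class-dependent spectral slowing.

Alzheimer's disease shifts scalp EEG power toward low frequencies: delta
and theta power rise while alpha, beta and gamma power fall, with MCI
intermediate between healthy controls and AD. This module generates
labeled multichannel recordings whose class-conditional spectra carry
exactly that structure, so the downstream feature/augmentation/
classification pipeline can be exercised and validated end to end on
data with a known ground truth.

Each channel is a unit-variance mixture of

* a 1/f^a-shaped Gaussian background,
* five band-limited Gaussian components (delta/theta/alpha/beta/gamma),
  each scaled by the square root of the class's relative band-power gain,
* a narrowband eyes-closed alpha oscillation at ``alpha_peak_hz``,

scaled to ``amplitude_uv`` overall RMS. Channels are weakly correlated
through a fixed convex mixture with one shared component. Band edges are
imported from the features module so generator and analyzer always agree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .features import DEFAULT_BANDS
from .types import CHANNELS_1020, Diagnosis, EEGRecording

__all__ = [
    "SpectralProfile",
    "CohortSpec",
    "default_profile",
    "default_profiles",
    "synthesize_recording",
    "generate_cohort",
]

_BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)

# Power budget of the unit-variance mixture: 1/f background, broadband
# band-limited components, and the narrowband alpha peak.
_W_BACKGROUND = 0.15
_W_BROADBAND = 0.60
_W_ALPHA_PEAK = 0.25

#: Default channel mixing weight: each channel is
#: sqrt(1-w)*independent + sqrt(w)*shared, giving pairwise correlation ~w.
DEFAULT_MIXING_WEIGHT = 0.2


@dataclass(frozen=True)
class SpectralProfile:
    """Class-conditional spectral recipe for one diagnostic group.

    ``band_gains`` are dimensionless relative-power multipliers on the five
    canonical bands; ``pink_exponent`` is the 1/f^a background slope;
    ``alpha_peak_hz`` centers the oscillatory alpha component;
    ``amplitude_uv`` is the overall RMS scale in microvolts.
    """

    band_gains: dict
    pink_exponent: float = 1.0
    alpha_peak_hz: float = 10.0
    amplitude_uv: float = 20.0

    def __post_init__(self) -> None:
        missing = set(_BAND_NAMES) - set(self.band_gains)
        if missing:
            raise ValueError(f"band_gains missing bands: {sorted(missing)}")
        if any(g <= 0 for g in self.band_gains.values()):
            raise ValueError("all band gains must be positive")
        if self.amplitude_uv <= 0:
            raise ValueError("amplitude_uv must be positive")
        if self.pink_exponent < 0:
            raise ValueError("pink_exponent must be >= 0")
        if not (8.0 <= self.alpha_peak_hz <= 13.0):
            raise ValueError("alpha_peak_hz must lie in the alpha band [8, 13]")

    def with_gain(self, band: str, gain: float) -> "SpectralProfile":
        gains = dict(self.band_gains)
        gains[band] = gain
        return replace(self, band_gains=gains)


# Gains chosen so the synthetic two-class problem is clearly learnable but
# not trivially saturated: AD raises delta/theta, lowers alpha/beta/gamma;
# MCI sits at the per-band geometric midpoint. The alpha peak slows mildly
# with disease severity.
_HC_GAINS = {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0}
_AD_GAINS = {"delta": 1.8, "theta": 1.8, "alpha": 0.55, "beta": 0.55, "gamma": 0.7}


def default_profile(label) -> SpectralProfile:
    """Built-in spectral profile for a diagnostic class.

    AD has strictly larger delta/theta gains and strictly smaller
    alpha/beta/gamma gains than HC; every MCI gain is the geometric
    midpoint of the HC and AD gains.
    """
    label = Diagnosis.coerce(label)
    if label is Diagnosis.HC:
        return SpectralProfile(band_gains=dict(_HC_GAINS), alpha_peak_hz=10.0)
    if label is Diagnosis.AD:
        return SpectralProfile(band_gains=dict(_AD_GAINS), alpha_peak_hz=9.0)
    mci = {b: float(np.sqrt(_HC_GAINS[b] * _AD_GAINS[b])) for b in _HC_GAINS}
    return SpectralProfile(band_gains=mci, alpha_peak_hz=9.5)


def default_profiles() -> dict:
    return {lab: default_profile(lab) for lab in Diagnosis}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and generation parameters.

    Defaults mirror a severely imbalanced clinical study population of
    102 HC / 7 MCI / 59 AD subjects recorded at 256 Hz.
    """

    n_hc: int = 102
    n_mci: int = 7
    n_ad: int = 59
    duration_s: float = 60.0
    fs_hz: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_mci, self.n_ad) < 0:
            raise ValueError("subject counts must be non-negative")
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration_s and fs_hz must be positive")
        n = self.duration_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs_hz must be a whole number of samples")


def _band_shares(pink_exponent: float) -> np.ndarray:
    """Relative broadband power per band from the 1/f^a integral over its edges."""
    shares = []
    for band in DEFAULT_BANDS:
        lo, hi = band.lo_hz, band.hi_hz
        if abs(pink_exponent - 1.0) < 1e-12:
            p = np.log(hi / lo)
        else:
            e = 1.0 - pink_exponent
            p = (hi**e - lo**e) / e
        shares.append(p)
    shares = np.asarray(shares, dtype=float)
    return shares / shares.sum()


def _pink_background(rng: np.random.Generator, n_rows: int, n_samples: int,
                     fs_hz: float, exponent: float) -> np.ndarray:
    """1/f^a-shaped Gaussian noise rows, unit RMS, band-limited to [1, fs/2]."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shape = np.zeros_like(freqs)
    nz = freqs >= 1.0  # avoid the 1/f singularity; matches the 1 Hz analysis floor
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    return _unit_rms(out)


def _unit_rms(rows: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(rows**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return rows / rms


def _bandlimited(rng: np.random.Generator, n_rows: int, n_samples: int,
                 fs_hz: float, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] by a zero-phase Butterworth."""
    nyq = fs_hz / 2.0
    sos = signal.butter(4, [lo_hz / nyq, min(hi_hz, nyq * 0.99) / nyq],
                        btype="bandpass", output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal((n_rows, n_samples)), axis=-1)
    return _unit_rms(x)


def synthesize_recording(profile: SpectralProfile, subject_id: str, label,
                         duration_s: float, fs_hz: float = 256.0,
                         n_channels: int = 19, seed: int = 0,
                         mixing_weight: float = DEFAULT_MIXING_WEIGHT,
                         channel_names=None) -> EEGRecording:
    """Generate one subject's recording from a spectral profile.

    Bit-identical output for identical arguments and seed. Channels are
    weakly correlated through a single shared component with convex power
    weight ``mixing_weight``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if fs_hz <= 2 * DEFAULT_BANDS[-1].hi_hz:
        raise ValueError(
            f"fs_hz must exceed {2 * DEFAULT_BANDS[-1].hi_hz} Hz so all five "
            "bands are representable"
        )
    if not (0.0 <= mixing_weight < 1.0):
        raise ValueError("mixing_weight must be in [0, 1)")
    n_samples = int(round(duration_s * fs_hz))
    rng = np.random.default_rng(seed)
    n_rows = n_channels + 1  # last row is the shared (common) component

    shares = _band_shares(profile.pink_exponent)
    sig = np.sqrt(_W_BACKGROUND) * _pink_background(
        rng, n_rows, n_samples, fs_hz, profile.pink_exponent)
    for band, share in zip(DEFAULT_BANDS, shares):
        gain = profile.band_gains[band.name]
        comp = _bandlimited(rng, n_rows, n_samples, fs_hz, band.lo_hz, band.hi_hz)
        sig += np.sqrt(_W_BROADBAND * share * gain) * comp
    alpha_gain = profile.band_gains["alpha"]
    peak = _bandlimited(rng, n_rows, n_samples, fs_hz,
                        profile.alpha_peak_hz - 1.0, profile.alpha_peak_hz + 1.0)
    sig += np.sqrt(_W_ALPHA_PEAK * alpha_gain) * peak

    common = sig[-1]
    data = (np.sqrt(1.0 - mixing_weight) * sig[:-1]
            + np.sqrt(mixing_weight) * common[None, :])
    data *= profile.amplitude_uv

    if channel_names is None:
        if n_channels == len(CHANNELS_1020):
            channel_names = CHANNELS_1020
        else:
            channel_names = tuple(f"CH{i + 1}" for i in range(n_channels))
    return EEGRecording(subject_id=subject_id, label=Diagnosis.coerce(label),
                        fs_hz=fs_hz, channel_names=channel_names, data=data)


def generate_cohort(spec: CohortSpec, profiles=None) -> list:
    """Generate a full labeled cohort; per-subject seeds derive from ``spec.seed``.

    Returns exactly ``n_hc + n_mci + n_ad`` recordings with unique subject ids
    (HC001..., MCI001..., AD001...).
    """
    if profiles is None:
        profiles = default_profiles()
    plan = [(Diagnosis.HC, spec.n_hc), (Diagnosis.MCI, spec.n_mci),
            (Diagnosis.AD, spec.n_ad)]
    for lab, count in plan:
        if count > 0 and lab not in profiles:
            raise ValueError(f"no spectral profile supplied for class {lab.value}")
    total = spec.n_hc + spec.n_mci + spec.n_ad
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(max(total, 1))
    recordings = []
    i = 0
    for lab, count in plan:
        for k in range(count):
            rec = synthesize_recording(
                profiles[lab], subject_id=f"{lab.value}{k + 1:03d}", label=lab,
                duration_s=spec.duration_s, fs_hz=spec.fs_hz,
                seed=int(child_seeds[i]))
            recordings.append(rec)
            i += 1
    return recordings
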