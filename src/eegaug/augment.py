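"""Minority-class training-set augmentation: noise addition, VAE, hybrid.

Three strategies generate artificial epochs for under-represented
diagnostic classes:

* **noise** — randomly selected real epochs of the class plus zero-mean
  Gaussian noise whose standard deviation is calibrated to the class
  (the rectified grand mean of the class's samples), or fixed;
* **vae** — samples decoded from a trained conditional VAE
  (:mod:`eegaug.vae`);
* **hybrid** — both kinds added simultaneously, with the noise arm using
  a small fixed sigma of 0.001 µV.

``balance_training_set`` applies the chosen strategy so every class is
raised to the majority-class count. Augmentation is applied to training
data only; splitting happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .types import Diagnosis, EpochSet, empty_epochset
from .vae import VAEModel, sample_vae

__all__ = [
    "SigmaMode",
    "AugmentMethod",
    "NoiseAugmentConfig",
    "HYBRID_NOISE_SIGMA",
    "class_mean_sigma",
    "add_noise_trials",
    "hybrid_augment",
    "balance_training_set",
]

#: Fixed noise standard deviation used by the hybrid method's noise arm (µV).
HYBRID_NOISE_SIGMA = 0.001

#: Floor on the calibrated sigma for degenerate (all-zero) classes.
SIGMA_FLOOR = 1e-6


class SigmaMode(str, Enum):
    CLASS_MEAN = "class_mean"
    FIXED = "fixed"


class AugmentMethod(str, Enum):
    NONE = "none"
    NOISE = "noise"
    VAE = "vae"
    HYBRID = "hybrid"


@dataclass(frozen=True)
class NoiseAugmentConfig:
    """Noise-addition settings. The noise mean is always zero; its standard
    deviation is either calibrated per class or fixed at ``sigma_fixed``.
    ``noise_scale`` multiplies the drawn noise (a zero value reproduces the
    zero-noise limit exactly)."""

    sigma_mode: SigmaMode = SigmaMode.CLASS_MEAN
    sigma_fixed: float = HYBRID_NOISE_SIGMA
    n_generate: int = 0
    seed: int = 0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_fixed <= 0:
            raise ValueError("sigma_fixed must be positive")
        if self.n_generate < 0:
            raise ValueError("n_generate must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def class_mean_sigma(eps: EpochSet, label) -> float:
    """Noise sigma calibrated to a class: the rectified grand mean |x| over
    all samples, channels and epochs of that class, floored at 1e-6.

    Band-passed EEG is effectively zero-mean, so the signed mean would be
    degenerate; the rectified mean is the natural amplitude scale (for a
    zero-mean Gaussian class it equals sigma * sqrt(2/pi)).
    """
    label = Diagnosis.coerce(label)
    mask = eps.labels == label
    if not mask.any():
        raise ValueError(f"no epochs labeled {label.value}")
    return max(float(np.mean(np.abs(eps.epochs[mask]))), SIGMA_FLOOR)


def add_noise_trials(eps: EpochSet, label,
                     cfg: NoiseAugmentConfig = NoiseAugmentConfig()) -> EpochSet:
    """Generate ``cfg.n_generate`` artificial epochs of one class.

    Each artificial epoch is a uniformly chosen source epoch of the class
    plus zero-mean Gaussian noise. Deterministic under ``cfg.seed``.
    """
    label = Diagnosis.coerce(label)
    mask = eps.labels == label
    if cfg.n_generate > 0 and not mask.any():
        raise ValueError(f"cannot augment: no epochs labeled {label.value}")
    if cfg.n_generate == 0:
        return empty_epochset(eps)
    if cfg.sigma_mode is SigmaMode.CLASS_MEAN:
        sigma = class_mean_sigma(eps, label)
    else:
        sigma = cfg.sigma_fixed
    source = eps.epochs[mask]
    rng = np.random.default_rng(cfg.seed)
    picks = rng.integers(0, source.shape[0], size=cfg.n_generate)
    noise = rng.standard_normal((cfg.n_generate,) + source.shape[1:])
    new = source[picks] + cfg.noise_scale * sigma * noise
    return EpochSet(
        epochs=new, fs_hz=eps.fs_hz, duration_s=eps.duration_s,
        labels=np.asarray([label] * cfg.n_generate, dtype=object),
        subject_ids=np.asarray(
            [f"NOISE_{label.value}_{i:04d}" for i in range(cfg.n_generate)],
            dtype=object),
        channel_names=eps.channel_names)


def hybrid_augment(eps: EpochSet, label, noise_cfg: NoiseAugmentConfig,
                   vae_model: VAEModel, n_noise: int, n_vae: int,
                   seed: int = 0) -> EpochSet:
    """Simultaneously add noise-based and VAE-based artificial epochs.

    The noise arm runs in fixed mode with sigma = 0.001 µV regardless of
    ``noise_cfg.sigma_mode``.
    """
    label = Diagnosis.coerce(label)
    noise_cfg = replace(noise_cfg, sigma_mode=SigmaMode.FIXED,
                        sigma_fixed=HYBRID_NOISE_SIGMA, n_generate=n_noise,
                        seed=seed)
    parts = []
    if n_noise > 0:
        parts.append(add_noise_trials(eps, label, noise_cfg))
    if n_vae > 0:
        parts.append(sample_vae(vae_model, label, n_vae, seed=seed + 1))
    if not parts:
        return empty_epochset(eps)
    return EpochSet.concatenate(parts)


def balance_training_set(train: EpochSet, method,
                         noise_cfg: NoiseAugmentConfig = NoiseAugmentConfig(),
                         vae_model: VAEModel | None = None,
                         seed: int = 0) -> EpochSet:
    """Raise every minority class to the majority-class epoch count.

    For each class with fewer epochs than the majority, (majority - count)
    artificial epochs are generated by ``method`` and appended. Method
    ``none`` returns the input unchanged; already balanced input is a
    fixed point for every method. Hybrid splits each deficit half noise
    (rounding up), half VAE.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    method = AugmentMethod(method)
    if method is AugmentMethod.NONE:
        return train
    if method in (AugmentMethod.VAE, AugmentMethod.HYBRID) and vae_model is None:
        raise ValueError(f"method {method.value} requires a trained VAE model")
    counts = train.class_counts()
    majority = max(counts.values())
    parts = [train]
    for lab in sorted(counts, key=lambda l: l.value):
        deficit = majority - counts[lab]
        if deficit == 0:
            continue
        lab_seed = int(np.random.SeedSequence(
            [seed, list(Diagnosis).index(lab)]).generate_state(1)[0] % (2**31))
        if method is AugmentMethod.NOISE:
            cfg = replace(noise_cfg, n_generate=deficit, seed=lab_seed)
            parts.append(add_noise_trials(train, lab, cfg))
        elif method is AugmentMethod.VAE:
            parts.append(sample_vae(vae_model, lab, deficit, seed=lab_seed))
        else:
            n_noise = (deficit + 1) // 2
            parts.append(hybrid_augment(train, lab, noise_cfg, vae_model,
                                        n_noise, deficit - n_noise,
                                        seed=lab_seed))
    return EpochSet.concatenate(parts)
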