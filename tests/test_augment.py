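"""Noise-addition calibration, hybrid policy, and minority balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegaug import (AugmentMethod, Diagnosis, NoiseAugmentConfig, SigmaMode,
                    add_noise_trials, balance_training_set, class_mean_sigma,
                    extract_features, hybrid_augment, train_vae, vae_loss)
from eegaug.vae import VAEConfig

from conftest import make_epochset


class TestClassMeanSigma:
    def test_all_ones_class(self):
        eps = make_epochset(["MCI", "MCI"])
        eps.epochs[:] = 1.0
        assert class_mean_sigma(eps, "MCI") == 1.0

    def test_zero_class_floored(self):
        eps = make_epochset(["MCI"])
        eps.epochs[:] = 0.0
        assert class_mean_sigma(eps, "MCI") == 1e-6

    def test_standard_normal_gives_rectified_mean(self):
        # E|X| = sqrt(2/pi) for X ~ N(0,1)
        eps = make_epochset(["MCI"] * 20, duration_s=10.0, seed=9)
        sigma = class_mean_sigma(eps, "MCI")
        assert abs(sigma - np.sqrt(2 / np.pi)) <= 0.02 * np.sqrt(2 / np.pi)

    def test_absent_class_raises(self):
        with pytest.raises(ValueError, match="MCI"):
            class_mean_sigma(make_epochset(["HC"]), "MCI")


class TestAddNoiseTrials:
    def test_zero_noise_limit_returns_exact_copies(self):
        eps = make_epochset(["MCI"] * 3, seed=1)
        cfg = NoiseAugmentConfig(sigma_mode=SigmaMode.FIXED, n_generate=10,
                                 seed=5, noise_scale=0.0)
        out = add_noise_trials(eps, "MCI", cfg)
        source = {e.tobytes() for e in eps.epochs}
        assert all(e.tobytes() in source for e in out.epochs)

    def test_count_and_label_contract(self):
        eps = make_epochset(["MCI"] * 3 + ["HC"] * 5, seed=2)
        out = add_noise_trials(eps, "MCI",
                               NoiseAugmentConfig(n_generate=25, seed=0))
        assert len(out) == 25
        assert all(l is Diagnosis.MCI for l in out.labels)

    def test_clt_mean_bound_single_source(self):
        eps = make_epochset(["MCI"], n_channels=1, duration_s=1.0, seed=3)
        cfg = NoiseAugmentConfig(sigma_mode=SigmaMode.FIXED, sigma_fixed=0.5,
                                 n_generate=1000, seed=7)
        out = add_noise_trials(eps, "MCI", cfg)
        dev = np.abs(out.epochs.mean(axis=0) - eps.epochs[0])
        assert dev.max() <= 4 * 0.5 / np.sqrt(1000)

    def test_deterministic_under_seed(self):
        eps = make_epochset(["MCI"] * 2, seed=4)
        cfg = NoiseAugmentConfig(n_generate=5, seed=11)
        a, b = (add_noise_trials(eps, "MCI", cfg) for _ in range(2))
        assert np.array_equal(a.epochs, b.epochs)

    def test_empty_class_with_generation_raises(self):
        with pytest.raises(ValueError, match="MCI"):
            add_noise_trials(make_epochset(["HC"]), "MCI",
                             NoiseAugmentConfig(n_generate=1))

    def test_small_sigma_preserves_spectral_profile(self, small_epochs):
        mci = small_epochs.select(
            np.asarray([l is Diagnosis.MCI for l in small_epochs.labels]))
        cfg = NoiseAugmentConfig(sigma_mode=SigmaMode.FIXED, sigma_fixed=0.001,
                                 n_generate=500, seed=1)
        art = add_noise_trials(mci, "MCI", cfg)
        p_src = extract_features(mci).X[:, :95].mean(axis=0)
        p_art = extract_features(art).X[:, :95].mean(axis=0)
        assert np.all(np.abs(p_art - p_src) <= 0.10 * p_src)


@pytest.fixture(scope="module")
def tiny_vae(small_epochs):
    return train_vae(small_epochs, VAEConfig(epochs=3, seed=0))


class TestHybridAndBalance:
    def test_hybrid_count_additivity(self, small_epochs, tiny_vae):
        out = hybrid_augment(small_epochs, "MCI", NoiseAugmentConfig(),
                             tiny_vae, n_noise=5, n_vae=7, seed=0)
        assert len(out) == 12
        assert all(l is Diagnosis.MCI for l in out.labels)

    def test_hybrid_empty(self, small_epochs, tiny_vae):
        out = hybrid_augment(small_epochs, "MCI", NoiseAugmentConfig(),
                             tiny_vae, n_noise=0, n_vae=0, seed=0)
        assert len(out) == 0

    def test_balance_equalizes_counts(self):
        eps = make_epochset(["HC"] * 40 + ["MCI"] * 5, seed=6)
        out = balance_training_set(eps, AugmentMethod.NOISE)
        counts = out.class_counts()
        assert counts[Diagnosis.HC] == counts[Diagnosis.MCI] == 40

    def test_method_none_is_identity(self):
        eps = make_epochset(["HC"] * 4 + ["MCI"] * 2, seed=7)
        assert balance_training_set(eps, "none") is eps

    def test_balanced_input_is_fixed_point(self):
        eps = make_epochset(["HC"] * 4 + ["MCI"] * 4, seed=8)
        out = balance_training_set(eps, AugmentMethod.NOISE)
        assert len(out) == len(eps)

    def test_vae_method_requires_model(self):
        eps = make_epochset(["HC"] * 4 + ["MCI"] * 2, seed=9)
        with pytest.raises(ValueError, match="VAE"):
            balance_training_set(eps, AugmentMethod.VAE)

    def test_balance_deterministic(self):
        eps = make_epochset(["HC"] * 6 + ["MCI"] * 2, seed=10)
        a = balance_training_set(eps, AugmentMethod.NOISE, seed=3)
        b = balance_training_set(eps, AugmentMethod.NOISE, seed=3)
        assert np.array_equal(a.epochs, b.epochs)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=1, max_size=8),
       st.lists(st.floats(-5, 5), min_size=1, max_size=8))
def test_kl_term_nonnegative(mu, logvar):
    d = min(len(mu), len(logvar))
    mu, logvar = np.asarray(mu[:d]), np.asarray(logvar[:d])
    x = np.zeros(3)
    _, _, kl = vae_loss(x, x, mu, logvar)
    assert kl >= -1e-12
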