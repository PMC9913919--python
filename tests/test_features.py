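"""Welch PSD, band averages, zero-crossing rate, and the 152-feature layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegaug import (DEFAULT_BANDS, BandDefinition, Diagnosis, WelchConfig,
                    band_integrated_psd, band_mean_psd, extract_features,
                    welch_psd, zcr)
from eegaug.types import CHANNELS_1020

from conftest import make_epochset


def brute_force_periodogram(x, fs):
    """Independent single-segment Hann-tapered periodogram (one-sided)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    # periodic Hann taper, mean removed, one-sided scaling
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)
    xd = (x - x.mean()) * w
    spec = np.abs(np.fft.rfft(xd)) ** 2 / (fs * np.sum(w**2))
    spec[1:] *= 2
    if n % 2 == 0:
        spec[-1] /= 2
    return np.fft.rfftfreq(n, 1 / fs), spec


class TestWelch:
    def test_psd_nonnegative(self):
        rng = np.random.default_rng(0)
        _, p = welch_psd(rng.standard_normal(1024), 128.0)
        assert p.min() >= 0

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(128 * 60)
        f, p = welch_psd(x, 128.0)
        total = np.sum(p) * (f[1] - f[0])
        assert abs(total - x.var()) <= 0.1 * x.var()

    def test_single_segment_matches_brute_force_periodogram(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(256)
        cfg = WelchConfig(segment_s=2.0, overlap_fraction=0.0)
        f, p = welch_psd(x, 128.0, cfg)
        f2, p2 = brute_force_periodogram(x, 128.0)
        assert np.allclose(f, f2)
        assert np.max(np.abs(p - p2)) <= 1e-10 * np.max(p2)

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(100), 128.0, WelchConfig(segment_s=2.0))


class TestBandMeanPsd:
    def test_constant_psd_gives_constant_mean(self):
        f = np.arange(0, 64.5, 0.5)
        p = np.full_like(f, 3.14)
        for band in DEFAULT_BANDS:
            assert band_mean_psd(f, p, band) == pytest.approx(3.14)

    def test_pure_alpha_tone_dominates(self):
        t = np.arange(1280) / 128.0
        x = np.sin(2 * np.pi * 10.0 * t)
        f, p = welch_psd(x, 128.0)
        alpha = band_mean_psd(f, p, DEFAULT_BANDS[2])
        for i, band in enumerate(DEFAULT_BANDS):
            if i != 2:
                assert alpha >= 100 * band_mean_psd(f, p, band)

    def test_out_of_range_band_raises(self):
        f = np.arange(0, 64.5, 0.5)
        with pytest.raises(ValueError, match="ultra"):
            band_mean_psd(f, np.ones_like(f), BandDefinition("ultra", 100, 110))


def test_band_partition_conserves_power(small_epochs):
    # the five bands partition [1, 50]: band integrals sum to the total
    f, p = welch_psd(small_epochs.epochs[0, 0], small_epochs.fs_hz)
    parts = sum(band_integrated_psd(f, p, b) for b in DEFAULT_BANDS)
    full = np.sum(p[(f >= 1.0) & (f <= 50.0)]) * (f[1] - f[0])
    assert abs(parts - full) <= 1e-9 * full


class TestZcr:
    def test_maximal_alternation(self):
        assert zcr(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0

    def test_constant_vector(self):
        assert zcr(np.full(10, 2.0)) == 0.0

    def test_single_cycle_sine_matches_direct_count(self):
        x = np.sin(2 * np.pi * np.arange(64) / 64)
        # direct count under the same sign convention (zeros inherit the
        # previous nonzero sign): only the mid-cycle crossing is interior
        signs = []
        prev = 0.0
        for v in x:
            s = np.sign(v) if v != 0 else prev
            signs.append(s)
            prev = s if s != 0 else prev
        expected = sum(a * b < 0 for a, b in zip(signs, signs[1:])) / 63
        assert expected == 1 / 63
        assert zcr(x) == pytest.approx(expected)

    def test_zero_plateau_does_not_count(self):
        assert zcr(np.array([1.0, 0.0, 0.0, 1.0])) == 0.0
        assert zcr(np.array([1.0, 0.0, -1.0])) == pytest.approx(0.5)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            zcr(np.array([1.0]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    def test_zcr_bounded(self, values):
        assert 0.0 <= zcr(np.asarray(values)) <= 1.0


class TestExtractFeatures:
    def test_19_channel_layout_is_152(self, small_epochs):
        fm = extract_features(small_epochs)
        assert fm.X.shape[1] == 152
        assert sum(n.endswith("_psd") for n in fm.feature_names) == 95
        assert sum(n.endswith(("_mean", "_var", "_zcr"))
                   for n in fm.feature_names) == 57
        assert fm.feature_names[0] == "FP1_delta_psd"
        assert fm.feature_names[95] == "FP1_mean"

    def test_single_channel_gives_8(self):
        fm = extract_features(make_epochset(["HC", "AD"], n_channels=1))
        assert fm.X.shape == (2, 8)

    def test_identical_epochs_identical_rows(self):
        eps = make_epochset(["HC", "HC"], seed=3)
        eps.epochs[1] = eps.epochs[0]
        fm = extract_features(eps)
        assert np.array_equal(fm.X[0], fm.X[1])

    def test_empty_epochset_raises(self, small_epochs):
        from eegaug.types import empty_epochset
        with pytest.raises(ValueError, match="empty"):
            extract_features(empty_epochset(small_epochs))

    def test_ad_delta_exceeds_hc_delta(self, small_epochs):
        # links generator to analyzer: spectral slowing is recoverable
        fm = extract_features(small_epochs)
        delta_cols = [i for i, n in enumerate(fm.feature_names)
                      if n.endswith("_delta_psd")]
        ad = fm.X[np.asarray([l is Diagnosis.AD for l in fm.labels])]
        hc = fm.X[np.asarray([l is Diagnosis.HC for l in fm.labels])]
        assert ad[:, delta_cols].mean() > hc[:, delta_cols].mean()

    def test_slowing_ratio_separates_classes(self, small_epochs):
        fm = extract_features(small_epochs)
        names = fm.feature_names

        def ratio(rows):
            low = rows[:, [i for i, n in enumerate(names)
                           if n.endswith(("_delta_psd", "_theta_psd"))]]
            high = rows[:, [i for i, n in enumerate(names)
                            if n.endswith(("_alpha_psd", "_beta_psd",
                                           "_gamma_psd"))]]
            return low.sum(axis=1).mean() / high.sum(axis=1).mean()

        ad = fm.X[np.asarray([l is Diagnosis.AD for l in fm.labels])]
        hc = fm.X[np.asarray([l is Diagnosis.HC for l in fm.labels])]
        assert ratio(ad) > ratio(hc)
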