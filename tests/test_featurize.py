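import numpy as np
import pytest
from scipy import signal as _sig

from affectstream.devices import Sample, builtin_profile
from affectstream.featurize import (
    BAND_NAMES,
    BANDS,
    FEATURES_PER_CHANNEL,
    RATIO_PAIRS,
    Window,
    WindowConfig,
    aligned_stimulus_intervals,
    extract_feature_vector,
    feature_names,
    power_ratios,
    shuffle_labeled_windows,
    tumbling_windows,
    welch_band_powers,
    windows_in_stimulus,
)


def _stream(n, sf=256.0, n_channels=2):
    return [Sample(i / sf, (0.0,) * n_channels) for i in range(n)]


class TestTumblingWindows:
    @pytest.mark.parametrize("n, expected", [(256, 1), (300, 1), (255, 0), (512, 2)])
    def test_window_counts(self, n, expected):
        cfg = WindowConfig(1.0, 256.0)
        wins = list(tumbling_windows(_stream(n), cfg))
        assert len(wins) == expected
        for w in wins:
            assert w.data.shape[0] == 256

    def test_window_times(self):
        cfg = WindowConfig(2.0, 256.0)
        wins = list(tumbling_windows(_stream(1024), cfg))
        assert [(w.t_start, w.t_end) for w in wins] == [(0.0, 2.0), (2.0, 4.0)]

    def test_fractional_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer sample count"):
            WindowConfig(0.3, 256.0)


class TestStimulusAlignment:
    def test_aligned_86_windows(self):
        # a 86.7-s stimulus at 1-s windows: 86 windows, last ending at t_end
        intervals = aligned_stimulus_intervals(10.0, 96.7, 1.0)
        assert len(intervals) == 86
        assert intervals[-1][1] == pytest.approx(96.7)
        assert intervals[0][0] == pytest.approx(10.7)

    def test_short_stimulus_no_windows(self):
        assert aligned_stimulus_intervals(10.0, 10.5, 1.0) == []

    def test_unaligned_whole_containment(self):
        wins = [
            Window(np.zeros((1, 1)), 9.5, 10.5),
            Window(np.zeros((1, 1)), 10.5, 11.5),
        ]
        kept = windows_in_stimulus(wins, 10.0, 12.0)
        assert [(w.t_start, w.t_end) for w in kept] == [(10.5, 11.5)]


class TestShuffle:
    def test_seed_determinism_and_multiset(self):
        items = [(i, i % 2) for i in range(50)]
        a = shuffle_labeled_windows(items, seed=3)
        b = shuffle_labeled_windows(items, seed=3)
        assert a == b
        assert sorted(a) == sorted(items)  # windows keep their own labels
        assert a != items  # a 50-item shuffle is virtually never identity

    def test_single_item_unchanged(self):
        assert shuffle_labeled_windows([("w", 1)], seed=0) == [("w", 1)]


class TestWelchBandPowers:
    def test_pure_10hz_dominates_alpha(self):
        t = np.arange(256) / 256.0
        w = np.sin(2 * np.pi * 10 * t)[:, None]
        powers = welch_band_powers(w, 256.0)[0]
        named = dict(zip(BAND_NAMES, powers[:5]))
        for band in ("delta", "theta", "beta", "gamma"):
            assert named["alpha"] > 10 * max(named[band], 1e-30)
        # independent oracle: the single-taper periodogram localizes the
        # sinusoid's power in the alpha band too
        f, p = _sig.periodogram(w[:, 0], fs=256.0)
        alpha_frac = p[(f >= 8) & (f < 16)].sum() / p.sum()
        assert alpha_frac > 0.99

    def test_zero_window_all_zero(self):
        powers = welch_band_powers(np.zeros((256, 3)), 256.0)
        np.testing.assert_array_equal(powers, 0.0)

    def test_white_noise_bands_partition_total(self, rng):
        w = rng.normal(size=(256, 2))
        powers = welch_band_powers(w, 256.0)
        np.testing.assert_allclose(powers[:, :5].sum(axis=1), powers[:, 5], rtol=1e-10)

    def test_total_at_least_max_band(self, rng):
        powers = welch_band_powers(rng.normal(size=(512, 3)), 256.0)
        assert np.all(powers[:, 5] >= powers[:, :5].max(axis=1) - 1e-12)

    def test_powers_nonnegative(self, rng):
        powers = welch_band_powers(rng.normal(size=(300, 4)), 256.0)
        assert np.all(powers >= 0)


class TestPowerRatios:
    def test_ten_pairs(self):
        assert len(RATIO_PAIRS) == 10
        out = power_ratios(np.ones((3, 5)))
        assert out.shape == (3, 10)

    def test_equal_bands_give_unit_ratios(self):
        out = power_ratios(np.full((1, 5), 7.0))
        np.testing.assert_allclose(out, 1.0, rtol=1e-9)

    def test_delta_numerator_ratios(self):
        bp = np.array([[2.0, 1.0, 1.0, 1.0, 1.0]])
        out = power_ratios(bp)[0]
        # first four pairs are (delta, *): ratio 2; the rest are 1
        np.testing.assert_allclose(out[:4], 2.0, rtol=1e-9)
        np.testing.assert_allclose(out[4:], 1.0, rtol=1e-9)

    def test_zero_denominator_guarded(self):
        out = power_ratios(np.zeros((1, 5)))
        assert np.all(np.isfinite(out))


class TestFeatureVector:
    @pytest.mark.parametrize(
        "device, expected", [("muse_s", 64), ("crown", 128), ("epoc", 224)]
    )
    def test_vector_length_per_device(self, device, expected, rng):
        profile = builtin_profile(device)
        cfg = WindowConfig(1.0, profile.sampling_rate)
        data = rng.normal(size=(cfg.n_samples, profile.n_channels))
        fv = extract_feature_vector(Window(data, 0.0, 1.0), profile, cfg)
        assert len(fv.values) == expected == FEATURES_PER_CHANNEL * profile.n_channels
        assert len(feature_names(profile)) == expected

    def test_amplitude_scaling_squares_powers_fixes_ratios(self, rng, muse):
        cfg = WindowConfig(1.0, 256.0)
        data = rng.normal(size=(256, 4))
        f1 = extract_feature_vector(Window(data, 0.0, 1.0), muse, cfg).values
        f2 = extract_feature_vector(Window(3.0 * data, 0.0, 1.0), muse, cfg).values
        per1 = f1.reshape(4, 16)
        per2 = f2.reshape(4, 16)
        np.testing.assert_allclose(per2[:, :6], 9.0 * per1[:, :6], rtol=1e-9)
        np.testing.assert_allclose(per2[:, 6:], per1[:, 6:], rtol=1e-6)

    def test_channel_mismatch_rejected(self, muse):
        cfg = WindowConfig(1.0, 256.0)
        with pytest.raises(ValueError, match="channels"):
            extract_feature_vector(Window(np.zeros((256, 3)), 0.0, 1.0), muse, cfg)
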