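"""Unit and property tests for the sifting decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nvcouple.emd import (DecompositionExhausted, Imf, SiftStop, decompose,
                          envelope_mean, find_extrema, peak_power_frequency,
                          sift, zero_crossing_count)


def brute_force_extrema(x):
    """Independent oracle: scan interior runs with plateau merging."""
    maxima, minima = [], []
    i = 1
    n = len(x)
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j < n - 1:  # plateau ends inside the array
            center = (i + j) // 2
            if x[i - 1] < x[i] and x[j + 1] < x[i]:
                maxima.append(center)
            elif x[i - 1] > x[i] and x[j + 1] > x[i]:
                minima.append(center)
        i = j + 1
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


class TestFindExtrema:
    def test_single_period_sine(self):
        t = np.linspace(0, 1, 101)[:-1]
        mx, mn = find_extrema(np.sin(2 * np.pi * t))
        assert len(mx) == 1 and len(mn) == 1

    def test_monotone_ramp_has_no_extrema(self):
        mx, mn = find_extrema(np.linspace(0, 1, 50))
        assert mx.size == 0 and mn.size == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        # quantized values create plateaus
        x = np.round(rng.standard_normal(50), 1)
        mx, mn = find_extrema(x)
        bx, bn = brute_force_extrema(x)
        np.testing.assert_array_equal(mx, bx)
        np.testing.assert_array_equal(mn, bn)

    def test_plateau_center_index(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, -1.0, 0.0])
        mx, mn = find_extrema(x)
        np.testing.assert_array_equal(mx, [2])
        np.testing.assert_array_equal(mn, [5])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            find_extrema(np.array([1.0, 2.0]))

    @settings(derandomize=True, max_examples=50)
    @given(arrays(np.float64, st.integers(3, 40),
                  elements=st.integers(-3, 3).map(float)))
    def test_property_matches_brute_force(self, x):
        mx, mn = find_extrema(x)
        bx, bn = brute_force_extrema(x)
        np.testing.assert_array_equal(mx, bx)
        np.testing.assert_array_equal(mn, bn)

    @settings(derandomize=True, max_examples=50)
    @given(arrays(np.float64, st.integers(3, 60),
                  elements=st.floats(-10, 10, allow_nan=False)))
    def test_property_maxima_exceed_neighbors(self, x):
        mx, mn = find_extrema(x)
        assert np.all(np.diff(mx) > 0) and np.all(np.diff(mn) > 0)
        for i in mx:
            assert 0 < i < len(x) - 1
            assert x[i] >= x[i - 1] and x[i] >= x[i + 1]


class TestEnvelopeMean:
    def _mean_of(self, x):
        mx, mn = find_extrema(x)
        return envelope_mean(x, mx, mn)

    def test_pure_sine_mean_near_zero(self):
        t = np.arange(0, 1.0, 1 / 500.0)  # 10 periods of 10 Hz at 500 Hz
        x = np.sin(2 * np.pi * 10 * t)
        m = self._mean_of(x)
        interior = slice(len(x) // 10, -len(x) // 10)
        assert np.max(np.abs(m[interior])) < 0.05

    def test_sine_plus_constant_recovers_constant(self):
        t = np.arange(0, 1.0, 1 / 500.0)
        c = 2.7
        m = self._mean_of(np.sin(2 * np.pi * 10 * t) + c)
        interior = slice(len(t) // 10, -len(t) // 10)
        assert np.allclose(m[interior], c, atol=0.05)

    def test_sine_with_trend_tracks_trend(self):
        t = np.arange(0, 1.0, 1 / 500.0)
        trend = 3.0 * t
        m = self._mean_of(np.sin(2 * np.pi * 10 * t) + trend)
        interior = slice(len(t) // 10, -len(t) // 10)
        assert np.max(np.abs(m[interior] - trend[interior])) < 0.1

    def test_insufficient_extrema_signals_exhaustion(self):
        x = np.linspace(0, 1, 30)
        with pytest.raises(DecompositionExhausted):
            envelope_mean(x, np.array([5]), np.array([2, 9]))


class TestSift:
    def test_fixed_point_on_pure_tone(self):
        t = np.arange(0, 2.0, 1 / 500.0)
        x = np.sin(2 * np.pi * 10 * t)
        imf = sift(x)
        interior = slice(len(x) // 10, -len(x) // 10)
        assert np.max(np.abs(imf.samples[interior] - x[interior])) < 0.05

    def test_two_tone_first_imf_is_fast_component(self):
        t = np.arange(0, 10.0, 1 / 500.0)
        fast = np.sin(2 * np.pi * 10 * t)
        x = fast + np.sin(2 * np.pi * 1 * t)
        imf = sift(x)
        lo, hi = len(t) // 10, -len(t) // 10
        r = np.corrcoef(imf.samples[lo:hi], fast[lo:hi])[0, 1]
        assert r > 0.95

    def test_stricter_threshold_never_fewer_iterations(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 5.0, 1 / 500.0)
        x = np.sin(2 * np.pi * 10 * t) + 0.5 * np.sin(2 * np.pi * 1 * t) \
            + 0.1 * rng.standard_normal(t.size)
        loose = sift(x, SiftStop(sd_threshold=0.2, s_number=10 ** 6))
        strict = sift(x, SiftStop(sd_threshold=0.02, s_number=10 ** 6))
        assert strict.sift_iterations >= loose.sift_iterations


class TestDecompose:
    def test_monotone_input_yields_no_imfs(self):
        x = np.linspace(0, 5, 100)
        s = decompose(x)
        assert len(s) == 0
        np.testing.assert_array_equal(s.residual, x)

    def test_two_tone_frequency_ordering(self):
        t = np.arange(0, 10.0, 1 / 500.0)
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 1 * t)
        s = decompose(x, sampling_rate=500.0)
        assert len(s) >= 2
        f1 = peak_power_frequency(s.imfs[0])
        f2 = peak_power_frequency(s.imfs[1])
        assert f1 > f2

    @pytest.mark.parametrize("seed", range(10))
    def test_completeness_on_random_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(500, 5000))
        t = np.arange(n) / 500.0
        x = np.zeros(n)
        for _ in range(int(rng.integers(1, 4))):
            x += rng.uniform(0.5, 2) * np.sin(
                2 * np.pi * rng.uniform(0.5, 100) * t + rng.uniform(0, 2 * np.pi))
        x += 0.5 * rng.standard_normal(n)
        s = decompose(x, sampling_rate=500.0)
        err = np.max(np.abs(s.reconstruct() - x))
        assert err < 1e-8 * np.ptp(x)

    def test_imf_condition_at_convergence(self):
        t = np.arange(0, 10.0, 1 / 500.0)
        x = np.sin(2 * np.pi * 10 * t) + 0.8 * np.sin(2 * np.pi * 1.3 * t)
        s = decompose(x, sampling_rate=500.0)
        for imf in s:
            mx, mn = find_extrema(imf.samples)
            n_ext = mx.size + mn.size
            assert abs(n_ext - zero_crossing_count(imf.samples)) <= 1

    def test_residual_is_nearly_monotone(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 10.0, 1 / 100.0)
        x = np.sin(2 * np.pi * 3 * t) + 0.3 * rng.standard_normal(t.size) + t
        s = decompose(x, sampling_rate=100.0)
        mx, mn = find_extrema(s.residual)
        assert mx.size + mn.size < 2

    def test_nan_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError):
            decompose(x)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            decompose(np.arange(5.0))


class TestPeakPowerFrequency:
    def _tone(self, f, fs=500.0, dur=10.0):
        t = np.arange(0, dur, 1 / fs)
        return Imf(np.sin(2 * np.pi * f * t), index=1, sampling_rate=fs)

    def test_pure_tone_within_one_bin(self):
        imf = self._tone(10.0)
        assert abs(peak_power_frequency(imf) - 10.0) <= 0.1  # bin width 1/10 s

    def test_60hz_tone_fails_50hz_screen(self):
        assert peak_power_frequency(self._tone(60.0)) > 50.0

    def test_white_noise_matches_independent_dft_argmax(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(1024)
        imf = Imf(x, index=1, sampling_rate=500.0)
        # independent oracle: explicit Hann window + rFFT magnitude
        w = 0.5 * (1 - np.cos(2 * np.pi * np.arange(x.size) / x.size))
        mag = np.abs(np.fft.rfft(x * w)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / 500.0)
        expected = freqs[1:][np.argmax(mag[1:])]
        assert peak_power_frequency(imf) == pytest.approx(expected)

    def test_all_zero_imf_returns_zero(self):
        imf = Imf(np.zeros(100), index=1, sampling_rate=500.0)
        assert peak_power_frequency(imf) == 0.0
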