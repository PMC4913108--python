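"""Tests for the per-trial coupling chain: screening, power, correlation."""

import numpy as np
import pytest

from nvcouple.coupling import (AnalysisParams, analyze_trial,
                               apply_significance_threshold, log_mean_power,
                               normalized_crosscorr, select_imfs)
from nvcouple.emd import Imf, ImfSet, decompose
from nvcouple.preprocess import Epoch


def _tone_imf(freq, index, fs=500.0, dur=10.0):
    t = np.arange(0, dur, 1 / fs)
    return Imf(np.sin(2 * np.pi * freq * t), index=index, sampling_rate=fs)


def brute_force_crosscorr(x, y, lag_n):
    """Direct per-lag implementation of the biased normalized estimator."""
    n = len(x)
    x0 = x - x.mean()
    y0 = y - y.mean()
    denom = n * x.std() * y.std()
    out = np.empty(2 * lag_n + 1)
    for i, k in enumerate(range(-lag_n, lag_n + 1)):
        acc = 0.0
        for t in range(n):
            if 0 <= t + k < n:
                acc += x0[t + k] * y0[t]
        out[i] = acc / denom
    return out


class TestSelectImfs:
    def test_50hz_screen_on_known_peaks(self):
        imfs = [_tone_imf(f, i + 1) for i, f in enumerate((60, 20, 4, 0.1))]
        s = ImfSet(imfs=imfs, residual=np.zeros(imfs[0].n), source_length=imfs[0].n)
        kept = select_imfs(s, cutoff=50.0)
        assert [imf.index for imf in kept] == [2, 3, 4]

    def test_nirs_rate_series_fully_retained(self):
        rng = np.random.default_rng(0)
        s = decompose(rng.standard_normal(500), sampling_rate=10.0)
        kept = select_imfs(s, cutoff=50.0)
        assert len(kept) == len(s)  # Nyquist 5 Hz < 50 Hz

    def test_matches_independent_filter(self):
        rng = np.random.default_rng(1)
        s = decompose(rng.standard_normal(4000), sampling_rate=500.0)
        from nvcouple.emd import peak_power_frequency
        expected = [i.index for i in s if peak_power_frequency(i) <= 50.0]
        assert [i.index for i in select_imfs(s)] == expected


class TestLogMeanPower:
    def test_constant_imf_closed_form(self):
        a = 3.0
        imf = Imf(np.full(25000, a), index=1, sampling_rate=500.0)
        ps = log_mean_power(imf, 10.0)
        assert ps.values.shape == (500,)
        np.testing.assert_allclose(ps.values, np.log10(a ** 2), atol=1e-12)

    def test_output_length_50s_epoch(self):
        imf = Imf(np.random.default_rng(0).standard_normal(25000), index=1,
                  sampling_rate=500.0)
        ps = log_mean_power(imf, 10.0)
        assert ps.values.size == 500 and ps.sampling_rate == 10.0

    def test_amplitude_step_gives_log4_jump(self):
        fs = 500.0
        t = np.arange(0, 10.0, 1 / fs)
        a = np.where(t < 5.0, 1.0, 2.0)
        imf = Imf(a * np.sin(2 * np.pi * 10 * t), index=1, sampling_rate=fs)
        ps = log_mean_power(imf, 10.0)
        jump = np.median(ps.values[55:95]) - np.median(ps.values[5:45])
        assert jump == pytest.approx(np.log10(4.0), abs=1e-6)

    def test_all_zero_imf_stays_finite(self):
        imf = Imf(np.zeros(1000), index=1, sampling_rate=500.0)
        ps = log_mean_power(imf, 10.0)
        assert np.all(np.isfinite(ps.values))

    def test_non_integer_ratio_rejected(self):
        imf = Imf(np.zeros(1000), index=1, sampling_rate=500.0)
        with pytest.raises(ValueError):
            log_mean_power(imf, 7.0)


class TestNormalizedCrosscorr:
    def test_self_correlation_peaks_at_zero(self, rng):
        x = rng.standard_normal(500)
        ccg = normalized_crosscorr(x, x, max_lag=20.0, rate=10.0)
        lag, r = max(zip(ccg.lags, ccg.r), key=lambda p: p[1])
        assert lag == 0.0
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_delayed_copy_peaks_at_minus_15s(self, rng):
        # y is x delayed by 150 samples at 10 Hz: x leads -> negative lag
        n, d = 500, 150
        base = rng.standard_normal(n + d)
        x = base[d:]          # x[t] = base[t+d]
        y = base[:n]          # y[t] = base[t] = x[t-d]
        ccg = normalized_crosscorr(x, y, max_lag=20.0, rate=10.0)
        peak_lag = ccg.lags[np.argmax(ccg.r)]
        assert peak_lag == pytest.approx(-15.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 200))
        ccg = normalized_crosscorr(x, y, max_lag=5.0, rate=10.0)
        expected = brute_force_crosscorr(x, y, 50)
        np.testing.assert_allclose(ccg.r, expected, atol=1e-12)

    def test_swap_mirrors_lag_axis(self, rng):
        x, y = rng.standard_normal((2, 300))
        fwd = normalized_crosscorr(x, y, max_lag=10.0, rate=10.0)
        rev = normalized_crosscorr(y, x, max_lag=10.0, rate=10.0)
        np.testing.assert_allclose(fwd.r, rev.r[::-1], atol=1e-12)

    def test_shift_equivariance(self, rng):
        n, m = 400, 30
        base = rng.standard_normal(n + m)
        x, y = base[:n], base[:n]
        lag0 = normalized_crosscorr(x, y, 20.0, 10.0)
        x_delayed = base[m:n + m]  # x advanced by m samples
        lag1 = normalized_crosscorr(x_delayed, y, 20.0, 10.0)
        p0 = lag0.lags[np.argmax(lag0.r)]
        p1 = lag1.lags[np.argmax(lag1.r)]
        assert p1 - p0 == pytest.approx(-m / 10.0, abs=0.1)

    def test_zero_variance_flagged(self):
        ccg = normalized_crosscorr(np.ones(100), np.arange(100.0), 2.0, 10.0)
        assert ccg.zero_variance
        assert np.all(ccg.r == 0.0)

    def test_lag_grid_spans_max_lag(self, rng):
        ccg = normalized_crosscorr(*rng.standard_normal((2, 500)), 20.0, 10.0)
        assert ccg.lags[0] == -20.0 and ccg.lags[-1] == 20.0
        assert np.all(np.abs(ccg.r) <= 1.0 + 1e-12)


class TestSignificanceThreshold:
    def test_bound_closed_form(self, rng):
        ccg = normalized_crosscorr(*rng.standard_normal((2, 500)), 20.0, 10.0)
        out = apply_significance_threshold(ccg, n_std=3)
        assert out.bound == pytest.approx(3 / np.sqrt(500), abs=1e-4)
        assert out.bound == pytest.approx(0.1342, abs=1e-4)

    def test_only_zeroes_never_alters(self, rng):
        ccg = normalized_crosscorr(*rng.standard_normal((2, 300)), 10.0, 10.0)
        out = apply_significance_threshold(ccg)
        surviving = out.r_thresholded != 0
        np.testing.assert_array_equal(out.r_thresholded[surviving],
                                      out.r[surviving])
        assert np.all(np.abs(out.r[~surviving]) < out.bound)

    def test_idempotent(self, rng):
        ccg = normalized_crosscorr(*rng.standard_normal((2, 300)), 10.0, 10.0)
        once = apply_significance_threshold(ccg)
        import dataclasses
        twice = apply_significance_threshold(
            dataclasses.replace(once, r=once.r_thresholded))
        np.testing.assert_array_equal(once.r_thresholded, twice.r_thresholded)

    def test_all_zero_input_unchanged(self):
        ccg = normalized_crosscorr(np.zeros(100), np.zeros(100), 2.0, 10.0)
        out = apply_significance_threshold(ccg)
        assert np.all(out.r_thresholded == 0.0)

    def test_null_survival_fraction_small(self):
        # white-noise pairs: the 3 SD rule should pass very few lag bins
        rng = np.random.default_rng(99)
        survived = total = 0
        for _ in range(100):
            x, y = rng.standard_normal((2, 500))
            ccg = apply_significance_threshold(
                normalized_crosscorr(x, y, 20.0, 10.0))
            survived += int(np.count_nonzero(ccg.r_thresholded))
            total += ccg.lags.size
        assert survived / total <= 0.02


class TestAnalyzeTrial:
    def _epochs(self, seed=0, rejected=False):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 50.0, 1 / 500.0)
        eeg = Epoch(samples=np.sin(2 * np.pi * 10 * t) + 0.3 * rng.standard_normal(t.size),
                    sampling_rate=500.0, trial_id=1, hemisphere="left",
                    source_channel="F3", interval=(0.0, 50.0), rejected=rejected)
        tn = np.arange(0, 50.0, 0.1)
        nirs = Epoch(samples=np.sin(2 * np.pi * 0.05 * tn) + 0.1 * rng.standard_normal(tn.size),
                     sampling_rate=10.0, trial_id=1, hemisphere="left",
                     source_channel="rSO2_left", interval=(0.0, 50.0))
        return eeg, nirs

    def test_rejected_epoch_gives_empty_result(self):
        eeg, nirs = self._epochs(rejected=True)
        assert analyze_trial(eeg, nirs) == []

    def test_index_pairs_are_subset_of_all_pairs(self):
        eeg, nirs = self._epochs()
        by_index = analyze_trial(eeg, nirs, AnalysisParams(pairing="index"))
        by_all = analyze_trial(eeg, nirs, AnalysisParams(pairing="all"))
        assert {c.pair for c in by_index} <= {c.pair for c in by_all}
        assert all(a == b for a, b in (c.pair for c in by_index))

    def test_correlograms_carry_metadata(self):
        eeg, nirs = self._epochs()
        out = analyze_trial(eeg, nirs)
        assert out, "expected at least one pair"
        for c in out:
            assert c.trial_id == 1 and c.hemisphere == "left"
            assert c.r_thresholded is not None
            assert np.isfinite(c.eeg_peak_hz) and np.isfinite(c.nirs_peak_hz)

    def test_mismatched_trials_rejected(self):
        eeg, nirs = self._epochs()
        nirs.trial_id = 2
        with pytest.raises(ValueError):
            analyze_trial(eeg, nirs)
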