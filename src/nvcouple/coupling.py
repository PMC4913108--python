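"""Per-trial neurovascular-coupling estimation.

For each analyzable trial: decompose the EEG and rSO2 epochs into IMFs,
discard EEG IMFs whose spectral peak exceeds 50 Hz, convert each retained
EEG IMF into a log10 mean-power series at the NIRS rate (10 Hz), and
cross-correlate NIRS IMFs against EEG power series over lags of +/-20 s.
Correlation values smaller in magnitude than an estimation-error bound of
``n_std`` standard errors (white-noise SE = 1/sqrt(N)) are set to zero.

Lag convention: with x = NIRS IMF and y = EEG power series,
r(k) = sum_t (x[t+k]-xbar)(y[t]-ybar) / (N*sx*sy), so a NEGATIVE peak lag
means the NIRS component temporally leads the EEG band power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .emd import Imf, ImfSet, SiftStop, decompose, peak_power_frequency
from .preprocess import Epoch

logger = logging.getLogger(__name__)

__all__ = [
    "PowerSeries",
    "CrossCorrelogram",
    "AnalysisParams",
    "select_imfs",
    "log_mean_power",
    "normalized_crosscorr",
    "apply_significance_threshold",
    "analyze_trial",
]


@dataclass
class PowerSeries:
    """log10 mean power of one EEG IMF, windowed down to the NIRS rate."""

    values: np.ndarray
    sampling_rate: float
    imf_index: int
    trial_id: int = 0


@dataclass
class CrossCorrelogram:
    """Normalized lagged cross-correlation for one (NIRS IMF, EEG IMF) pair."""

    lags: np.ndarray              # seconds, symmetric grid
    r: np.ndarray
    n: int                        # sample count of the input series
    bound: float = 0.0            # significance half-width (0 until thresholded)
    r_thresholded: np.ndarray | None = None
    nirs_imf_index: int = 0
    eeg_imf_index: int = 0
    trial_id: int = 0
    hemisphere: str = ""
    hemisphere_trial: int = 0
    nirs_peak_hz: float = np.nan   # spectral peak of the NIRS IMF
    eeg_peak_hz: float = np.nan    # spectral peak of the EEG IMF
    zero_variance: bool = False

    @property
    def pair(self) -> tuple[int, int]:
        return (self.nirs_imf_index, self.eeg_imf_index)

    @property
    def imf_index(self) -> int:
        """Single index view for same-index pairings."""
        return self.nirs_imf_index

    def peak(self, use_thresholded: bool = True) -> tuple[float, float]:
        """(lag_s, r) of the maximum correlation value."""
        vals = self.r_thresholded if (use_thresholded and
                                      self.r_thresholded is not None) else self.r
        i = int(np.argmax(vals))
        return float(self.lags[i]), float(vals[i])


@dataclass(frozen=True)
class AnalysisParams:
    """Tunables of the per-trial analysis chain."""

    cutoff_hz: float = 50.0        # discard IMFs with spectral peak above this
    max_lag_s: float = 20.0
    n_std: float = 3.0
    bound_mode: str = "fixed"      # 'fixed': n_std/sqrt(N); 'lag': n_std/sqrt(N-|k|)
    pairing: str = "index"         # 'index', 'rank', or 'all'
    max_imfs: int | None = 12
    stop: SiftStop = SiftStop()
    power_floor_rel: float = 1e-12  # floor for log, relative to epoch mean power


def select_imfs(imfset: ImfSet, cutoff: float = 50.0) -> list[Imf]:
    """IMFs whose periodogram peak is at or below ``cutoff`` Hz.

    High-frequency IMFs carry line noise, EMG and broadband instrument noise
    rather than band-limited cortical rhythms; the 50 Hz screen removes
    them.  Original 1-based indices are preserved on the returned IMFs.
    """
    return [imf for imf in imfset if peak_power_frequency(imf) <= cutoff]


def log_mean_power(imf: Imf, target_rate: float = 10.0,
                   floor_rel: float = 1e-12) -> PowerSeries:
    """log10 of windowed mean power, resampled to ``target_rate``.

    Consecutive non-overlapping windows of rate/target_rate samples are
    averaged after squaring (50 samples per window for 500 -> 10 Hz); the
    window mean power is floored at ``floor_rel`` times the epoch mean power
    so the log stays finite when a window is exactly zero.
    """
    ratio = imf.sampling_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"sampling rate {imf.sampling_rate} is not an integer multiple "
            f"of target rate {target_rate}")
    w = int(round(ratio))
    x = imf.samples
    nwin = x.size // w
    p = (x[:nwin * w] ** 2).reshape(nwin, w).mean(axis=1)
    epoch_power = float(np.mean(x ** 2))
    floor = max(floor_rel * epoch_power, np.finfo(float).tiny)
    return PowerSeries(values=np.log10(np.maximum(p, floor)),
                       sampling_rate=target_rate, imf_index=imf.index)


def normalized_crosscorr(x: np.ndarray, y: np.ndarray, max_lag: float = 20.0,
                         rate: float = 10.0) -> CrossCorrelogram:
    """Biased normalized cross-correlation on a symmetric lag grid.

    r(k) = sum over the valid overlap of (x[t+k]-xbar)(y[t]-ybar),
    divided by N*sx*sy with the divisor fixed at N (the estimator standard
    econometric cross-correlation routines use), for
    k = -max_lag*rate .. +max_lag*rate.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    lag_n = int(round(max_lag * rate))
    if n <= lag_n:
        raise ValueError("series shorter than the requested maximum lag")
    lags = np.arange(-lag_n, lag_n + 1) / rate
    sx = float(x.std())
    sy = float(y.std())
    if sx == 0.0 or sy == 0.0:
        logger.warning("zero-variance input: returning all-zero correlogram")
        return CrossCorrelogram(lags=lags, r=np.zeros(lags.size), n=n,
                                zero_variance=True)
    x0 = x - x.mean()
    y0 = y - y.mean()
    full = sps.correlate(x0, y0, mode="full", method="auto")
    k = sps.correlation_lags(n, n, mode="full")
    sel = (k >= -lag_n) & (k <= lag_n)
    r = full[sel] / (n * sx * sy)
    return CrossCorrelogram(lags=lags, r=r, n=n)


def apply_significance_threshold(ccg: CrossCorrelogram, n_std: float = 3.0,
                                 bound_mode: str = "fixed") -> CrossCorrelogram:
    """Zero correlation values within ``n_std`` estimation-error SDs of zero.

    Under the null of uncorrelated series the correlation estimate at any
    lag has standard error about 1/sqrt(N) (white-noise bound); values with
    |r| below n_std/sqrt(N) are treated as noise and set to zero.  With
    ``bound_mode='lag'`` the bound grows with |lag| as n_std/sqrt(N-|k|),
    reflecting the shrinking overlap.  Idempotent; surviving values are
    passed through unchanged.
    """
    base = n_std / np.sqrt(ccg.n)
    if bound_mode == "fixed":
        bound = base
        mask = np.abs(ccg.r) < bound
    elif bound_mode == "lag":
        dlag = ccg.lags[1] - ccg.lags[0] if ccg.lags.size > 1 else 1.0
        k = np.abs(np.round(ccg.lags / dlag)).astype(int)
        per_lag = n_std / np.sqrt(np.maximum(ccg.n - k, 1))
        bound = base
        mask = np.abs(ccg.r) < per_lag
    else:
        raise ValueError("bound_mode must be 'fixed' or 'lag'")
    thresholded = np.where(mask, 0.0, ccg.r)
    return replace(ccg, bound=float(bound), r_thresholded=thresholded)


def analyze_trial(eeg_epoch: Epoch, nirs_epoch: Epoch,
                  params: AnalysisParams = AnalysisParams()
                  ) -> list[CrossCorrelogram]:
    """Full per-trial chain: EMD, screening, power series, correlograms.

    Pairing modes:

    * ``'index'`` (default): NIRS IMF i with EEG IMF i (original extraction
      index), for every i where both exist and the EEG IMF survived the
      50 Hz screen — matching timescale ranks across modalities;
    * ``'rank'``: k-th NIRS IMF with k-th *retained* EEG IMF;
    * ``'all'``: every retained combination.

    A rejected epoch yields an empty list (logged), so artifact trials
    appear downstream as missing rather than as zeros.
    """
    if eeg_epoch.rejected or nirs_epoch.rejected:
        logger.info("trial %d skipped: %s", eeg_epoch.trial_id,
                    eeg_epoch.reject_reason or nirs_epoch.reject_reason)
        return []
    if eeg_epoch.trial_id != nirs_epoch.trial_id:
        raise ValueError("EEG and NIRS epochs belong to different trials")

    eeg_set = decompose(eeg_epoch.samples, max_imfs=params.max_imfs,
                        stop=params.stop, sampling_rate=eeg_epoch.sampling_rate)
    nirs_set = decompose(nirs_epoch.samples, max_imfs=params.max_imfs,
                         stop=params.stop, sampling_rate=nirs_epoch.sampling_rate)
    eeg_kept = select_imfs(eeg_set, cutoff=params.cutoff_hz)
    nirs_kept = select_imfs(nirs_set, cutoff=params.cutoff_hz)
    eeg_peaks = {imf.index: peak_power_frequency(imf) for imf in eeg_kept}
    nirs_peaks = {imf.index: peak_power_frequency(imf) for imf in nirs_kept}

    power = {imf.index: log_mean_power(imf, target_rate=nirs_epoch.sampling_rate,
                                       floor_rel=params.power_floor_rel)
             for imf in eeg_kept}
    nirs_by_index = {imf.index: imf for imf in nirs_kept}

    if params.pairing == "index":
        pairs = [(i, i) for i in nirs_by_index if i in power]
    elif params.pairing == "rank":
        eeg_sorted = sorted(power)
        nirs_sorted = sorted(nirs_by_index)
        pairs = list(zip(nirs_sorted, eeg_sorted))
    elif params.pairing == "all":
        pairs = [(i, j) for i in sorted(nirs_by_index) for j in sorted(power)]
    else:
        raise ValueError("pairing must be 'index', 'rank', or 'all'")

    out: list[CrossCorrelogram] = []
    for ni, ei in pairs:
        ccg = normalized_crosscorr(nirs_by_index[ni].samples, power[ei].values,
                                   max_lag=params.max_lag_s,
                                   rate=nirs_epoch.sampling_rate)
        ccg = apply_significance_threshold(ccg, n_std=params.n_std,
                                           bound_mode=params.bound_mode)
        ccg.nirs_imf_index = ni
        ccg.eeg_imf_index = ei
        ccg.trial_id = eeg_epoch.trial_id
        ccg.hemisphere = eeg_epoch.hemisphere
        ccg.hemisphere_trial = eeg_epoch.hemisphere_trial
        ccg.nirs_peak_hz = nirs_peaks[ni]
        ccg.eeg_peak_hz = eeg_peaks[ei]
        out.append(ccg)
    return out
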