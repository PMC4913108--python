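"""Empirical Mode Decomposition by iterative sifting.

EMD adaptively splits a signal into intrinsic mode functions (IMFs): locally
narrow-band components satisfying (i) the number of extrema and the number of
zero crossings differ by at most one and (ii) the mean of the upper and lower
cubic-spline envelopes is approximately zero everywhere.  IMF 1 carries the
highest local frequencies; frequency content decreases with index, and the
final residual is monotone or single-humped.  The decomposition is complete:
the IMFs plus the residual sum back to the input to rounding precision.

Sifting stops on the classic Cauchy criterion (normalized squared change
between consecutive sifts below ``sd_threshold``) or on an S-number rule
(extrema and zero-crossing counts within one of each other for
``s_number`` consecutive iterations), whichever comes first, with a hard
iteration cap.  Envelope ends are stabilized by mirroring the two extrema
nearest each boundary about the end sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import periodogram

logger = logging.getLogger(__name__)

__all__ = [
    "Imf",
    "ImfSet",
    "SiftStop",
    "DecompositionExhausted",
    "find_extrema",
    "envelope_mean",
    "sift",
    "decompose",
    "peak_power_frequency",
    "zero_crossing_count",
]


class DecompositionExhausted(Exception):
    """Raised when a signal has too few extrema to build spline envelopes."""


@dataclass
class Imf:
    """A single intrinsic mode function.

    ``index`` is the 1-based extraction rank; lower index means higher
    frequency content.
    """

    samples: np.ndarray
    index: int
    sampling_rate: float
    sift_iterations: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class ImfSet:
    """Ordered IMFs plus the monotone (or single-hump) residual."""

    imfs: list[Imf]
    residual: np.ndarray
    source_length: int

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf.samples
        return out

    def __len__(self) -> int:
        return len(self.imfs)

    def __iter__(self):
        return iter(self.imfs)


@dataclass(frozen=True)
class SiftStop:
    """Stopping parameters for sifting.

    sd_threshold : Cauchy criterion bound, sum((h_prev-h)^2)/sum(h_prev^2).
    s_number     : consecutive iterations with |#extrema - #zero crossings|
                   <= 1 required for the S-number stop.
    max_iterations : hard cap; hitting it logs a warning, never raises.
    """

    sd_threshold: float = 0.2
    s_number: int = 3
    max_iterations: int = 200


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict interior local maxima and minima of ``x``.

    Equal-valued plateaus count once, at their center sample (left-center for
    even plateau lengths), which makes extremum placement deterministic.
    Returns (maxima_indices, minima_indices), each strictly increasing.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples to define interior extrema")
    # Run-length encode so plateaus become single nodes.
    change = np.empty(x.size, dtype=bool)
    change[0] = True
    np.not_equal(x[1:], x[:-1], out=change[1:])
    starts = np.flatnonzero(change)          # first index of each run
    vals = x[starts]
    if vals.size < 3:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:] - 1               # last index of each run
    ends[-1] = x.size - 1
    centers = (starts + ends) // 2
    left = vals[:-2]
    mid = vals[1:-1]
    right = vals[2:]
    maxima = centers[1:-1][(mid > left) & (mid > right)]
    minima = centers[1:-1][(mid < left) & (mid < right)]
    return maxima.astype(np.intp), minima.astype(np.intp)


def zero_crossing_count(x: np.ndarray) -> int:
    """Number of sign changes, ignoring exact zeros inside runs."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _mirrored_knots(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema by reflecting the two nearest each end about the end sample."""
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    knots = np.concatenate([left_i, idx, right_i])
    values = np.concatenate([left_v, val, right_v])
    # Mirroring an extremum at the exact end sample would duplicate a knot.
    keep = np.empty(knots.size, dtype=bool)
    keep[0] = True
    np.greater(knots[1:], knots[:-1], out=keep[1:])
    return knots[keep], values[keep]


def envelope_mean(x: np.ndarray, maxima: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Pointwise mean of the cubic-spline upper and lower envelopes.

    The upper envelope interpolates the maxima, the lower the minima, each
    extended by mirroring the two nearest extrema about both ends.  Raises
    :class:`DecompositionExhausted` when either side has fewer than two
    extrema, which signals the caller that sifting cannot proceed.
    """
    x = np.asarray(x, dtype=np.float64)
    if maxima.size < 2 or minima.size < 2:
        raise DecompositionExhausted(
            f"{maxima.size} maxima / {minima.size} minima: envelopes undefined")
    n = x.size
    t = np.arange(n)
    ik, vk = _mirrored_knots(maxima, x[maxima], n)
    upper = CubicSpline(ik, vk)(t)
    ik, vk = _mirrored_knots(minima, x[minima], n)
    lower = CubicSpline(ik, vk)(t)
    return 0.5 * (upper + lower)


def sift(x: np.ndarray, stop: SiftStop = SiftStop()) -> Imf:
    """Extract one IMF candidate from ``x`` by iterative envelope removal.

    Iterates ``h <- h - envelope_mean(h)`` until the Cauchy criterion drops
    below ``stop.sd_threshold`` or the S-number rule holds, capped at
    ``stop.max_iterations`` (a warning is logged on hitting the cap and the
    current ``h`` is returned).
    """
    h = np.asarray(x, dtype=np.float64).copy()
    stable = 0
    iterations = 0
    for iteration in range(stop.max_iterations):
        maxima, minima = find_extrema(h)
        try:
            m = envelope_mean(h, maxima, minima)
        except DecompositionExhausted:
            break
        h_new = h - m
        denom = float(np.dot(h, h))
        sd = float(np.dot(m, m)) / denom if denom > 0 else 0.0
        h = h_new
        iterations = iteration + 1
        if sd < stop.sd_threshold:
            break
        n_ext = maxima.size + minima.size
        if abs(n_ext - zero_crossing_count(h)) <= 1:
            stable += 1
            if stable >= stop.s_number:
                break
        else:
            stable = 0
    else:
        logger.warning("sifting hit the %d-iteration cap without converging",
                       stop.max_iterations)
    return Imf(h, index=0, sampling_rate=0.0, sift_iterations=iterations)


def decompose(x: np.ndarray, max_imfs: int | None = None,
              stop: SiftStop = SiftStop(), sampling_rate: float = 1.0) -> ImfSet:
    """Full EMD of ``x``: IMFs extracted in order until the residual is trivial.

    Extraction stops when the residual has fewer than two maxima or two
    minima (monotone or single-hump) or when ``max_imfs`` is reached.  The
    completeness identity  sum(IMFs) + residual == x  holds to rounding
    precision because the residual is formed by running subtraction.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 10:
        raise ValueError("input too short for decomposition (need >= 10 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or Inf")
    residual = x.copy()
    imfs: list[Imf] = []
    while max_imfs is None or len(imfs) < max_imfs:
        maxima, minima = find_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        imf = sift(residual, stop)
        imf.index = len(imfs) + 1
        imf.sampling_rate = sampling_rate
        residual = residual - imf.samples
        imfs.append(imf)
    return ImfSet(imfs=imfs, residual=residual, source_length=x.size)


def peak_power_frequency(imf: Imf) -> float:
    """Frequency (Hz) of the periodogram maximum, zero bin excluded.

    Uses a single Hann-windowed periodogram: on short epochs this keeps the
    full frequency resolution that Welch averaging would trade away.  An
    all-zero IMF has no spectral peak and returns 0.0.
    """
    x = imf.samples
    if x.size < 16:
        raise ValueError("IMF too short for a spectral estimate (need >= 16)")
    if not np.any(x):
        return 0.0
    freqs, pxx = periodogram(x, fs=imf.sampling_rate, window="hann",
                             detrend=False)
    return float(freqs[1:][np.argmax(pxx[1:])])
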