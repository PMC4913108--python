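"""Shared containers for synchronized physiological recordings.

A session couples multichannel EEG (500 Hz) with two-channel regional
cerebral oxygen saturation (rSO2, 10 Hz) under a randomized block design of
transcranial direct-current stimulation (tDCS): each trial is a ramp-up, an
ON plateau, a ramp-down, and an OFF rest period, alternating hemispheres in
random order.  All times are seconds from session start; intervals follow
the half-open convention [start, end) so that sample counts are exact at
integer-ratio sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "Trial", "TrialSchedule"]


@dataclass
class TimeSeries:
    """Uniformly sampled single-channel data."""

    name: str
    rate: float  # Hz
    data: np.ndarray  # 1-D float64
    start: float = 0.0  # seconds, time of first sample

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 1:
            raise ValueError("TimeSeries data must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.data.size

    @property
    def end(self) -> float:
        """Exclusive end time: start + n/rate."""
        return self.start + self.n / self.rate

    def times(self) -> np.ndarray:
        return self.start + np.arange(self.n) / self.rate

    def crop(self, t0: float, t1: float) -> "TimeSeries":
        """Samples with t0 <= t < t1 (half-open)."""
        i0 = int(np.ceil((t0 - self.start) * self.rate - 1e-9))
        i1 = int(np.ceil((t1 - self.start) * self.rate - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n)
        if i1 < i0:
            i1 = i0
        return TimeSeries(self.name, self.rate, self.data[i0:i1],
                          start=self.start + i0 / self.rate)

    def covers(self, t0: float, t1: float) -> bool:
        return t0 >= self.start - 1e-9 and t1 <= self.end + 1e-9


@dataclass
class Trial:
    """One stimulation block: ramp-up, ON plateau, ramp-down, OFF rest."""

    index: int  # 1-based position in the session
    hemisphere: str
    ramp_up_start: float
    on_start: float
    on_end: float
    off_start: float
    off_end: float

    @property
    def hemisphere_index(self) -> int | None:
        """1-based index within this trial's hemisphere; set by the schedule."""
        return getattr(self, "_hemisphere_index", None)


@dataclass
class TrialSchedule:
    """Ordered trials plus the protocol constants they were built from."""

    trials: list[Trial]
    on_duration: float = 50.0
    ramp_duration: float = 5.0
    off_duration: float = 60.0

    def __post_init__(self) -> None:
        counters: dict[str, int] = {}
        for tr in self.trials:
            counters[tr.hemisphere] = counters.get(tr.hemisphere, 0) + 1
            tr._hemisphere_index = counters[tr.hemisphere]

    @property
    def order(self) -> list[str]:
        return [t.hemisphere for t in self.trials]

    @property
    def hemispheres(self) -> list[str]:
        seen: list[str] = []
        for t in self.trials:
            if t.hemisphere not in seen:
                seen.append(t.hemisphere)
        return seen

    def for_hemisphere(self, label: str) -> list[Trial]:
        return [t for t in self.trials if t.hemisphere == label]

    @property
    def span(self) -> tuple[float, float]:
        return (self.trials[0].ramp_up_start, self.trials[-1].off_end)

    def to_dict(self) -> dict:
        return {
            "on_duration": self.on_duration,
            "ramp_duration": self.ramp_duration,
            "off_duration": self.off_duration,
            "trials": [
                {
                    "index": t.index,
                    "hemisphere": t.hemisphere,
                    "ramp_up_start": t.ramp_up_start,
                    "on_start": t.on_start,
                    "on_end": t.on_end,
                    "off_start": t.off_start,
                    "off_end": t.off_end,
                }
                for t in self.trials
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSchedule":
        trials = [Trial(**{k: v for k, v in t.items()}) for t in d["trials"]]
        return cls(trials, on_duration=d["on_duration"],
                   ramp_duration=d["ramp_duration"],
                   off_duration=d["off_duration"])
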