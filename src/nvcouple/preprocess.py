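"""Raw session recordings -> per-trial analysis epochs.

Three steps: crop each trial's OFF rest period to its middle window
(default: drop 5 s leading and 5 s trailing of the 60 s OFF, keeping 50 s),
spatially re-reference the EEG center electrode against the average of its
surround electrodes, and screen epochs for artifacts.  The artifact screen
is an automated two-rule stand-in for visual inspection: an absolute
amplitude rule and a local-variance rule, both configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .session import TimeSeries, TrialSchedule

logger = logging.getLogger(__name__)

__all__ = ["Epoch", "extract_off_epochs", "surround_reference", "reject_artifacts"]


@dataclass
class Epoch:
    """One trial's analysis window of a single channel."""

    samples: np.ndarray
    sampling_rate: float
    trial_id: int            # 1-based session-wide index
    hemisphere: str
    source_channel: str
    interval: tuple[float, float]  # absolute seconds, half-open
    hemisphere_trial: int = 0      # 1-based index within the hemisphere
    rejected: bool = False
    reject_reason: str | None = None

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]

    @property
    def n(self) -> int:
        return self.samples.size


def extract_off_epochs(series: TimeSeries, schedule: TrialSchedule,
                       lead_trim: float = 5.0, trail_trim: float = 5.0
                       ) -> list[Epoch]:
    """Middle-OFF epoch of every trial, half-open [off_start+lead, off_end-trail).

    A trial whose trimmed OFF window is not fully covered by the recording
    yields a rejected, empty epoch (per-trial error record) rather than
    failing the whole extraction.
    """
    if lead_trim + trail_trim >= schedule.off_duration:
        raise ValueError("trims must leave a positive analysis window")
    epochs: list[Epoch] = []
    for tr in schedule.trials:
        t0 = tr.off_start + lead_trim
        t1 = tr.off_end - trail_trim
        if not series.covers(t0, t1):
            logger.warning("trial %d OFF window [%.1f, %.1f) outside recording "
                           "span [%.1f, %.1f)", tr.index, t0, t1,
                           series.start, series.end)
            epochs.append(Epoch(np.empty(0), series.rate, tr.index,
                                tr.hemisphere, series.name, (t0, t1),
                                hemisphere_trial=tr.hemisphere_index or 0,
                                rejected=True,
                                reject_reason="off-interval outside recording"))
            continue
        cropped = series.crop(t0, t1)
        epochs.append(Epoch(cropped.data, series.rate, tr.index, tr.hemisphere,
                            series.name, (t0, t1),
                            hemisphere_trial=tr.hemisphere_index or 0))
    return epochs


def surround_reference(channels: dict[str, TimeSeries], center: str,
                       surround: list[str]) -> TimeSeries:
    """Center channel minus the average of its surround channels.

    This surround (small-Laplacian) reference localizes the montage's
    sensitivity to the cortex under the center electrode.
    """
    missing = [name for name in [center, *surround] if name not in channels]
    if missing:
        raise ValueError(f"missing channel(s): {', '.join(missing)}")
    c = channels[center]
    for name in surround:
        s = channels[name]
        if s.n != c.n or s.rate != c.rate:
            raise ValueError(f"channel {name} length/rate differs from {center}")
    mean = np.mean([channels[name].data for name in surround], axis=0)
    out = TimeSeries(name=f"{center}-avg({','.join(surround)})",
                     rate=c.rate, data=c.data - mean, start=c.start)
    return out


def reject_artifacts(epoch: Epoch, amp_threshold: float = 100.0,
                     var_ratio: float = 25.0) -> Epoch:
    """Flag an epoch as artifactual; never modifies the samples.

    Rules (either trips the flag):
    * amplitude: max |sample - median| > ``amp_threshold`` (signal units);
    * variance:  any 1 s window's variance > ``var_ratio`` times the median
      1 s-window variance of the epoch.

    Flagged epochs are excluded downstream but retained in reports.
    """
    if epoch.rejected or epoch.n == 0:
        return epoch
    x = epoch.samples
    reason = None
    if np.max(np.abs(x - np.median(x))) > amp_threshold:
        reason = "amplitude"
    else:
        w = int(round(epoch.sampling_rate))  # 1 s windows
        if w >= 2 and x.size >= 2 * w:
            nwin = x.size // w
            v = x[:nwin * w].reshape(nwin, w).var(axis=1)
            med = np.median(v)
            if med > 0 and np.max(v) > var_ratio * med:
                reason = "variance"
    if reason is None:
        return epoch
    return replace(epoch, rejected=True, reject_reason=reason)
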