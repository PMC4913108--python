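"""Synthetic tDCS joint-imaging sessions with known (planted) coupling.

Real recordings of this protocol are single-patient and not public, so the
generator emulates them with a ground-truth record attached: every
downstream stage can then be validated by parameter recovery.

Per hemisphere the generative model is

* a slow latent hemodynamic process ``s(t)`` — unit-variance Gaussian noise
  band-limited to 0.03-0.08 Hz;
* rSO2(t) = baseline + a_c * s(t) + Mayer (~0.1 Hz) + respiratory (~0.25 Hz)
  + cardiac (~1 Hz) sinusoids + white noise, clipped to a physiological band;
* EEG center channel = env(t) * sin(2*pi*f_carrier*t + phase) + 1/f noise
  + white noise, where from the coupling-onset trial onward
  env(t) = A * max(env_floor, 1 + gain * depth * s(t - |lag|)) and before
  onset env(t) = A.  The rSO2 slow component therefore temporally LEADS the
  EEG amplitude envelope by |planted_lag| seconds (negative lag convention:
  NIRS leads EEG band power).

Surround electrodes carry independent noise, so surround-average referencing
preserves the planted carrier.  Designated artifact trials receive 2-5 s
transients of ten times the carrier amplitude inside the analyzed OFF
window, exercising the artifact screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .session import TimeSeries, Trial, TrialSchedule

__all__ = [
    "SessionConfig",
    "SyntheticSession",
    "LEFT_EEG_CHANNELS",
    "RIGHT_EEG_CHANNELS",
    "make_trial_order",
    "generate_session",
]

#: montage used by the study: center channel first, then its surround
LEFT_EEG_CHANNELS = ("F3", "F1", "FC3", "F5")
RIGHT_EEG_CHANNELS = ("F4", "F2", "FC4", "F6")

_HEMISPHERES = ("left", "right")


def _per_hemisphere(value, cast=float) -> dict[str, float]:
    """Accept a scalar or a {'left':..,'right':..} mapping."""
    if isinstance(value, dict):
        return {h: cast(value[h]) for h in _HEMISPHERES}
    return {h: cast(value) for h in _HEMISPHERES}


@dataclass
class SessionConfig:
    """Knobs of the generative model; defaults mirror the study protocol.

    ``planted_lag`` is seconds, negative meaning the NIRS slow component
    leads the EEG power envelope.  ``coupling_onset_trial`` is the 1-based
    hemisphere-local trial index at which coupling switches on (at the first
    sample of that trial's ON plateau).  Scalars for per-hemisphere fields
    apply to both hemispheres.
    """

    n_trials_per_hemisphere: int = 15
    on_duration: float = 50.0
    ramp_duration: float = 5.0
    off_duration: float = 60.0
    eeg_rate: int = 500
    nirs_rate: int = 10
    planted_lag: float | dict = -15.0
    coupling_onset_trial: int | dict = 11
    coupling_gain: float = 1.0
    mayer_amp: float = 0.4       # % rSO2
    resp_amp: float = 0.3        # % rSO2
    cardiac_amp: float = 0.2     # % rSO2
    eeg_noise_sd: float = 2.0    # uV, white
    artifact_trials: frozenset[int] = frozenset()  # session-wide 1-based ids
    rng_seed: int = 0
    # documented free parameters (no values reported for the patient)
    nirs_baseline: float = 65.0      # % rSO2
    nirs_coupling_amp: float = 1.5   # % rSO2 per unit latent s
    nirs_noise_sd: float = 0.3       # % rSO2, white
    slow_band: tuple[float, float] = (0.03, 0.08)  # Hz, latent passband
    carrier_freq: float = 10.0       # Hz, coupled EEG oscillation
    carrier_amp: float = 10.0        # uV
    modulation_depth: float = 0.6    # envelope modulation per unit s at gain 1
    envelope_floor: float = 0.05     # rectification floor, fraction of carrier_amp
    pink_amp: float = 3.0            # uV rms of 1/f background
    coupling_mode: str = "nirs_leads"  # or "eeg_leads"

    def validate(self) -> None:
        if self.n_trials_per_hemisphere < 1:
            raise ValueError("n_trials_per_hemisphere must be >= 1")
        for name in ("on_duration", "ramp_duration", "off_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eeg_rate <= 0 or self.nirs_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.eeg_rate % self.nirs_rate != 0:
            raise ValueError("eeg_rate must be an integer multiple of nirs_rate")
        for h, k in self.onset_by_hemisphere().items():
            if not 1 <= k <= self.n_trials_per_hemisphere:
                raise ValueError(
                    f"coupling_onset_trial[{h}]={k} outside 1..{self.n_trials_per_hemisphere}")
        if self.coupling_gain < 0:
            raise ValueError("coupling_gain must be >= 0")
        if self.coupling_mode not in ("nirs_leads", "eeg_leads"):
            raise ValueError("coupling_mode must be 'nirs_leads' or 'eeg_leads'")

    def lag_by_hemisphere(self) -> dict[str, float]:
        return _per_hemisphere(self.planted_lag)

    def onset_by_hemisphere(self) -> dict[str, int]:
        return _per_hemisphere(self.coupling_onset_trial, cast=int)

    @property
    def trial_length(self) -> float:
        return 2 * self.ramp_duration + self.on_duration + self.off_duration

    @property
    def session_length(self) -> float:
        return 2 * self.n_trials_per_hemisphere * self.trial_length


@dataclass
class SyntheticSession:
    """Generated recordings, their schedule, and the planted ground truth."""

    eeg: dict[str, TimeSeries]
    nirs: dict[str, TimeSeries]      # keyed 'left'/'right', units % rSO2
    schedule: TrialSchedule
    truth: dict
    config: SessionConfig


def make_trial_order(n_per_hemisphere: int, rng_seed: int) -> list[str]:
    """Randomized block order: each hemisphere exactly n times, shuffled.

    Deterministic in ``rng_seed``.
    """
    if n_per_hemisphere < 1:
        raise ValueError("n_per_hemisphere must be >= 1")
    labels = np.array(["left"] * n_per_hemisphere + ["right"] * n_per_hemisphere)
    rng = np.random.default_rng(rng_seed)
    return list(labels[rng.permutation(labels.size)])


def _build_schedule(order: list[str], cfg: SessionConfig) -> TrialSchedule:
    trials = []
    t = 0.0
    for i, hemi in enumerate(order, start=1):
        trials.append(Trial(
            index=i, hemisphere=hemi,
            ramp_up_start=t,
            on_start=t + cfg.ramp_duration,
            on_end=t + cfg.ramp_duration + cfg.on_duration,
            off_start=t + 2 * cfg.ramp_duration + cfg.on_duration,
            off_end=t + cfg.trial_length,
        ))
        t += cfg.trial_length
    return TrialSchedule(trials, on_duration=cfg.on_duration,
                         ramp_duration=cfg.ramp_duration,
                         off_duration=cfg.off_duration)


def _bandlimited_noise(n: int, rate: float, band: tuple[float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to ``band`` by FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, rate: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise with the requested rms (flat below 0.1 Hz)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shape = 1.0 / np.sqrt(np.maximum(f, 0.1))
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _gamma_kernel(rate: float, peak: float, duration: float = 40.0) -> np.ndarray:
    """Unit-area gamma-variate impulse response peaking at ``peak`` seconds."""
    t = np.arange(0.0, duration, 1.0 / rate)
    shape = 4.0
    scale = peak / (shape - 1.0)
    k = t ** (shape - 1) * np.exp(-t / scale)
    return k / k.sum()


def generate_session(config: SessionConfig) -> SyntheticSession:
    """Simulate one full two-hemisphere session; see module docstring.

    Bit-identical output for identical (config, seed).
    """
    cfg = config
    cfg.validate()
    root = np.random.SeedSequence(cfg.rng_seed)
    # independent, reproducible streams per purpose
    seeds = {name: np.random.default_rng(s) for name, s in zip(
        ("order", "latent_left", "latent_right", "nirs_left", "nirs_right",
         "eeg_left", "eeg_right", "surround", "artifact"),
        root.spawn(9))}

    # trial order depends only on the scalar seed, per the order contract
    order = make_trial_order(cfg.n_trials_per_hemisphere,
                             rng_seed=cfg.rng_seed)
    schedule = _build_schedule(order, cfg)
    total = cfg.session_length
    n_nirs = int(round(total * cfg.nirs_rate))
    n_eeg = int(round(total * cfg.eeg_rate))
    t_nirs = np.arange(n_nirs) / cfg.nirs_rate
    t_eeg = np.arange(n_eeg) / cfg.eeg_rate

    lags = cfg.lag_by_hemisphere()
    onsets = cfg.onset_by_hemisphere()
    pad = max(30.0, max(abs(v) for v in lags.values()) + 10.0)
    n_pad = int(round(pad * cfg.nirs_rate))

    eeg: dict[str, TimeSeries] = {}
    nirs: dict[str, TimeSeries] = {}
    truth_onset_time = {}

    for hemi, channels in (("left", LEFT_EEG_CHANNELS), ("right", RIGHT_EEG_CHANNELS)):
        rng_lat = seeds[f"latent_{hemi}"]
        rng_nirs = seeds[f"nirs_{hemi}"]
        rng_eeg = seeds[f"eeg_{hemi}"]
        # latent slow process on a padded grid so its delayed copy is defined
        s_ext = _bandlimited_noise(n_nirs + 2 * n_pad, cfg.nirs_rate,
                                   cfg.slow_band, rng_lat)
        t_ext = (np.arange(n_nirs + 2 * n_pad) - n_pad) / cfg.nirs_rate
        s = s_ext[n_pad:n_pad + n_nirs]

        # hemisphere-local onset time: first sample of the ON plateau
        k = onsets[hemi]
        onset_trial = schedule.for_hemisphere(hemi)[k - 1]
        onset_time = onset_trial.on_start
        truth_onset_time[hemi] = onset_time

        phases = rng_nirs.uniform(0, 2 * np.pi, size=3)
        if cfg.coupling_mode == "nirs_leads":
            slow_nirs = s
            env_source = np.interp(t_eeg - abs(lags[hemi]), t_ext, s_ext)
        else:  # eeg_leads: rSO2 follows EEG power through a gamma kernel
            env_source = np.interp(t_eeg, t_ext, s_ext)
            kernel = _gamma_kernel(cfg.nirs_rate, peak=abs(lags[hemi]))
            conv = np.convolve(s_ext, kernel)[:s_ext.size]
            slow = conv[n_pad:n_pad + n_nirs]
            sd = slow.std()
            slow_nirs = slow / sd if sd > 0 else slow

        r = (cfg.nirs_baseline
             + cfg.nirs_coupling_amp * slow_nirs
             + cfg.mayer_amp * np.sin(2 * np.pi * 0.1 * t_nirs + phases[0])
             + cfg.resp_amp * np.sin(2 * np.pi * 0.25 * t_nirs + phases[1])
             + cfg.cardiac_amp * np.sin(2 * np.pi * 1.0 * t_nirs + phases[2])
             + cfg.nirs_noise_sd * rng_nirs.standard_normal(n_nirs))
        np.clip(r, 40.0, 90.0, out=r)
        nirs[hemi] = TimeSeries(name=f"rSO2_{hemi}", rate=cfg.nirs_rate, data=r)

        gate = (t_eeg >= onset_time).astype(np.float64)
        env = cfg.carrier_amp * np.maximum(
            cfg.envelope_floor,
            1.0 + cfg.coupling_gain * cfg.modulation_depth * env_source * gate)
        phase = rng_eeg.uniform(0, 2 * np.pi)
        carrier = env * np.sin(2 * np.pi * cfg.carrier_freq * t_eeg + phase)
        center = (carrier
                  + _pink_noise(n_eeg, cfg.eeg_rate, cfg.pink_amp, rng_eeg)
                  + cfg.eeg_noise_sd * rng_eeg.standard_normal(n_eeg))
        eeg[channels[0]] = TimeSeries(channels[0], cfg.eeg_rate, center)
        for name in channels[1:]:
            noise = (_pink_noise(n_eeg, cfg.eeg_rate, cfg.pink_amp, seeds["surround"])
                     + cfg.eeg_noise_sd * seeds["surround"].standard_normal(n_eeg))
            eeg[name] = TimeSeries(name, cfg.eeg_rate, noise)

    # artifact transients inside the analyzed middle-OFF window of the
    # designated trials, on that trial's center electrode
    rng_art = seeds["artifact"]
    for trial_id in sorted(cfg.artifact_trials):
        if not 1 <= trial_id <= len(schedule.trials):
            raise ValueError(f"artifact trial {trial_id} outside the session")
        tr = schedule.trials[trial_id - 1]
        dur = rng_art.uniform(2.0, 5.0)
        lo = tr.off_start + cfg.ramp_duration
        hi = tr.off_end - cfg.ramp_duration - dur
        start = rng_art.uniform(lo, hi)
        center_name = (LEFT_EEG_CHANNELS if tr.hemisphere == "left"
                       else RIGHT_EEG_CHANNELS)[0]
        ts = eeg[center_name]
        i0 = int(round(start * cfg.eeg_rate))
        i1 = int(round((start + dur) * cfg.eeg_rate))
        burst = 10.0 * cfg.carrier_amp * rng_art.standard_normal(i1 - i0)
        ts.data[i0:i1] += burst

    truth = {
        "planted_lag_s": lags,
        "coupling_onset_trial": onsets,
        "coupling_onset_time_s": truth_onset_time,
        "coupling_gain": cfg.coupling_gain,
        "coupling_mode": cfg.coupling_mode,
        "artifact_trials": sorted(cfg.artifact_trials),
        "rng_seed": cfg.rng_seed,
    }
    return SyntheticSession(eeg=eeg, nirs=nirs, schedule=schedule,
                            truth=truth, config=cfg)
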