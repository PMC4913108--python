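"""File formats, run configuration, and the end-to-end pipeline driver.

CSV dialect for time series: comma-separated, UTF-8, '.' decimal, header
row, first column ``time_s``, one column per channel.  Schedules, ground
truth, reports and run manifests are JSON.  EEG may alternatively be read
from EDF (via :mod:`mne`); a minimal 16-bit EDF writer is included so
sessions can be exported without extra dependencies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coupling import AnalysisParams, CrossCorrelogram, analyze_trial
from .emd import SiftStop
from .preprocess import extract_off_epochs, reject_artifacts, surround_reference
from .report import CouplingReport, build_report
from .session import TimeSeries, TrialSchedule
from .synthetic import LEFT_EEG_CHANNELS, RIGHT_EEG_CHANNELS, SyntheticSession

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_session",
    "write_session",
    "write_edf",
    "read_eeg_edf",
    "correlograms_to_frame",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


@dataclass
class RunConfig:
    """Every tunable of the analysis pipeline, fail-closed on unknown keys."""

    # preprocessing
    lead_trim: float = 5.0
    trail_trim: float = 5.0
    amp_threshold: float = 100.0    # uV
    var_ratio: float = 25.0
    montage: dict = field(default_factory=lambda: {
        "left": {"center": "F3", "surround": list(LEFT_EEG_CHANNELS[1:])},
        "right": {"center": "F4", "surround": list(RIGHT_EEG_CHANNELS[1:])},
    })
    # coupling analysis
    cutoff_hz: float = 50.0
    max_lag_s: float = 20.0
    n_std: float = 3.0
    bound_mode: str = "fixed"
    pairing: str = "index"
    max_imfs: int = 12
    sd_threshold: float = 0.2
    s_number: int = 3
    max_iterations: int = 200
    power_floor_rel: float = 1e-12
    # report
    pair_selection: str = "coherence"     # or 'count'
    min_eeg_peak_hz: float = 1.0
    onset_min_r: float | None = None      # None: the significance bound
    onset_lag_band: tuple[float, float] = (-20.0, 0.0)
    onset_persistence: float = 0.8
    # bookkeeping
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def analysis_params(self) -> AnalysisParams:
        return AnalysisParams(
            cutoff_hz=self.cutoff_hz, max_lag_s=self.max_lag_s,
            n_std=self.n_std, bound_mode=self.bound_mode, pairing=self.pairing,
            max_imfs=self.max_imfs,
            stop=SiftStop(sd_threshold=self.sd_threshold, s_number=self.s_number,
                          max_iterations=self.max_iterations),
            power_floor_rel=self.power_floor_rel)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**d)
        if isinstance(cfg.onset_lag_band, list):
            cfg.onset_lag_band = tuple(cfg.onset_lag_band)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["onset_lag_band"] = list(self.onset_lag_band)
        return d


# ---------------------------------------------------------------------------
# session serialization

def _write_timeseries_csv(path: Path, series: list[TimeSeries]) -> None:
    t = series[0].times()
    df = pd.DataFrame({"time_s": t})
    for s in series:
        if s.n != series[0].n or s.rate != series[0].rate:
            raise ValueError("channels in one file must share length and rate")
        df[s.name] = s.data
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_timeseries_csv(path: Path) -> dict[str, TimeSeries]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: first column must be 'time_s'")
    if len(df) < 2:
        raise ValueError(f"{path}: too few rows to infer a sampling rate")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if np.any(~np.isfinite(t)) or np.any(dt <= 0):
        bad = int(np.argmax(~np.isfinite(t) if np.any(~np.isfinite(t)) else dt <= 0)) + 2
        raise ValueError(f"{path}: non-monotone or non-finite time_s near line {bad}")
    rate = 1.0 / float(np.median(dt))
    rate = round(rate, 9)
    if np.max(np.abs(np.diff(t) - 1.0 / rate)) > 0.25 / rate:
        raise ValueError(f"{path}: time_s is not uniformly sampled")
    out = {}
    for col in df.columns:
        if col == "time_s":
            continue
        vals = df[col].to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(vals)):
            bad = int(np.argmax(~np.isfinite(vals))) + 2
            raise ValueError(f"{path}: non-finite value in column {col} at line {bad}")
        out[col] = TimeSeries(name=col, rate=rate, data=vals, start=float(t[0]))
    return out


def write_session(session: SyntheticSession, out_dir: str | Path,
                  edf: bool = False) -> dict[str, Path]:
    """Write a session as eeg.csv (or eeg.edf), nirs.csv and schedule.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    eeg_series = [session.eeg[k] for k in (*LEFT_EEG_CHANNELS, *RIGHT_EEG_CHANNELS)]
    if edf:
        paths["eeg"] = out / "eeg.edf"
        write_edf(paths["eeg"], eeg_series)
    else:
        paths["eeg"] = out / "eeg.csv"
        _write_timeseries_csv(paths["eeg"], eeg_series)
    paths["nirs"] = out / "nirs.csv"
    _write_timeseries_csv(paths["nirs"], [session.nirs["left"], session.nirs["right"]])
    paths["schedule"] = out / "schedule.json"
    meta = {"schedule": session.schedule.to_dict(), "truth": session.truth,
            "rates": {"eeg": session.config.eeg_rate, "nirs": session.config.nirs_rate}}
    paths["schedule"].write_text(json.dumps(meta, indent=1))
    return paths


def read_session(session_dir: str | Path
                 ) -> tuple[dict[str, TimeSeries], dict[str, TimeSeries],
                            TrialSchedule, dict]:
    """Load (eeg channels, nirs channels, schedule, truth-or-empty)."""
    d = Path(session_dir)
    sched_path = d / "schedule.json"
    if not sched_path.exists():
        raise FileNotFoundError(f"{sched_path} not found")
    meta = json.loads(sched_path.read_text())
    schedule = TrialSchedule.from_dict(meta["schedule"])
    if (d / "eeg.csv").exists():
        eeg = _read_timeseries_csv(d / "eeg.csv")
    elif (d / "eeg.edf").exists():
        eeg = read_eeg_edf(d / "eeg.edf")
    else:
        raise FileNotFoundError(f"no eeg.csv or eeg.edf in {d}")
    nirs_raw = _read_timeseries_csv(d / "nirs.csv")
    nirs = {}
    for name, ts in nirs_raw.items():
        key = "left" if "left" in name.lower() else ("right" if "right" in name.lower() else name)
        nirs[key] = ts
    declared = meta.get("rates", {})
    for label, group, key in (("eeg", eeg, "eeg"), ("nirs", nirs, "nirs")):
        want = declared.get(key)
        for ts in group.values():
            if want and abs(ts.rate - want) > 1e-6 * want:
                raise ValueError(f"{label} channel {ts.name}: rate {ts.rate} Hz "
                                 f"differs from declared {want} Hz")
    t0, t1 = schedule.span
    for ts in (*eeg.values(), *nirs.values()):
        if not ts.covers(t0, t0) or ts.end < t1 - 1.0 / ts.rate - 1e-9:
            raise ValueError(f"channel {ts.name} does not span the schedule "
                             f"[{t0}, {t1})")
    return eeg, nirs, schedule, meta.get("truth", {})


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit integer encoding

def write_edf(path: str | Path, series: list[TimeSeries]) -> None:
    """Minimal EDF writer: equal-rate channels, 1 s data records.

    Physical ranges are per-channel min/max, so quantization error is
    bounded by range/2^16.  Written because no EDF-writing library is a
    declared dependency; readable by any EDF tool.
    """
    rate = series[0].rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(rate))
    n_records = min(s.n for s in series) // spr
    ns = len(series)

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 + 256 * ns), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(ns), 4),
    ])
    phys_min = [float(np.floor(min(s.data.min(), -1.0))) for s in series]
    phys_max = [float(np.ceil(max(s.data.max(), 1.0))) for s in series]
    header += b"".join(pad(s.name[:16], 16) for s in series)
    header += b"".join(pad("", 80) for _ in series)          # transducer
    header += b"".join(pad("uV", 8) for _ in series)
    header += b"".join(pad(f"{m:g}", 8) for m in phys_min)
    header += b"".join(pad(f"{m:g}", 8) for m in phys_max)
    header += b"".join(pad("-32768", 8) for _ in series)
    header += b"".join(pad("32767", 8) for _ in series)
    header += b"".join(pad("", 80) for _ in series)          # prefiltering
    header += b"".join(pad(str(spr), 8) for _ in series)
    header += b"".join(pad("", 32) for _ in series)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for s, lo, hi in zip(series, phys_min, phys_max):
                chunk = s.data[rec * spr:(rec + 1) * spr]
                scaled = (chunk - lo) / (hi - lo) * 65535.0 - 32768.0
                fh.write(np.round(scaled).astype("<i2").tobytes())


def read_eeg_edf(path: str | Path) -> dict[str, TimeSeries]:
    """Read EEG channels from EDF via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    rate = float(raw.info["sfreq"])
    out = {}
    for name in raw.ch_names:
        data = raw.get_data(picks=[name])[0]
        # mne scales EDF 'uV'-dimensioned channels to volts
        out[name.strip()] = TimeSeries(name=name.strip(), rate=rate,
                                       data=data * 1e6)
    return out


# ---------------------------------------------------------------------------
# analysis outputs

def correlograms_to_frame(ccgs: list[CrossCorrelogram]) -> pd.DataFrame:
    """Tidy long-format view of per-trial correlograms."""
    rows = []
    for c in ccgs:
        thr = c.r_thresholded if c.r_thresholded is not None else np.full(c.lags.size, np.nan)
        rows.append(pd.DataFrame({
            "trial": c.trial_id, "hemisphere": c.hemisphere,
            "hemisphere_trial": c.hemisphere_trial,
            "nirs_imf": c.nirs_imf_index, "eeg_imf": c.eeg_imf_index,
            "lag_s": c.lags, "r": c.r, "r_thresholded": thr,
            "bound": c.bound,
        }))
    if not rows:
        return pd.DataFrame(columns=["trial", "hemisphere", "hemisphere_trial",
                                     "nirs_imf", "eeg_imf", "lag_s", "r",
                                     "r_thresholded", "bound"])
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: RunConfig,
                 eeg: dict[str, TimeSeries] | None = None,
                 nirs: dict[str, TimeSeries] | None = None,
                 schedule: TrialSchedule | None = None
                 ) -> tuple[CouplingReport, list[CrossCorrelogram], dict]:
    """Preprocess -> per-trial coupling -> aggregated report.

    Inputs may be passed in memory or loaded from ``config.input_dir``.
    Per-trial failures are recorded in the manifest; the run completes with
    partial results where possible.  Returns (report, correlograms,
    manifest).
    """
    t_start = time.time()
    if eeg is None or nirs is None or schedule is None:
        if config.input_dir is None:
            raise ValueError("either in-memory inputs or config.input_dir required")
        eeg, nirs, schedule, _truth = read_session(config.input_dir)

    params = config.analysis_params()
    manifest: dict = {"config": config.to_dict(), "errors": [], "timing_s": {},
                      "versions": _versions()}

    t0 = time.time()
    referenced: dict[str, TimeSeries] = {}
    for hemi, spec in config.montage.items():
        referenced[hemi] = surround_reference(eeg, spec["center"], spec["surround"])
    manifest["timing_s"]["reference"] = round(time.time() - t0, 3)

    t0 = time.time()
    ccgs: list[CrossCorrelogram] = []
    rejected: dict[str, list[int]] = {}
    for hemi in schedule.hemispheres:
        if hemi not in referenced or hemi not in nirs:
            manifest["errors"].append(f"hemisphere {hemi}: missing channels")
            continue
        eeg_epochs = extract_off_epochs(referenced[hemi], schedule,
                                        config.lead_trim, config.trail_trim)
        nirs_epochs = extract_off_epochs(nirs[hemi], schedule,
                                         config.lead_trim, config.trail_trim)
        for e_ep, n_ep in zip(eeg_epochs, nirs_epochs):
            if e_ep.hemisphere != hemi:
                continue
            e_ep = reject_artifacts(e_ep, config.amp_threshold, config.var_ratio)
            if e_ep.rejected or n_ep.rejected:
                rejected.setdefault(hemi, []).append(e_ep.hemisphere_trial)
                manifest["errors"].append(
                    f"trial {e_ep.trial_id} ({hemi}) rejected: "
                    f"{e_ep.reject_reason or n_ep.reject_reason}")
                continue
            try:
                ccgs.extend(analyze_trial(e_ep, n_ep, params))
            except Exception as exc:  # per-trial containment
                manifest["errors"].append(f"trial {e_ep.trial_id} ({hemi}): {exc}")
    manifest["timing_s"]["coupling"] = round(time.time() - t0, 3)

    t0 = time.time()
    report = build_report(ccgs, trial_order=schedule.order,
                          on_duration=schedule.on_duration,
                          pair_selection=config.pair_selection,
                          onset_min_r=config.onset_min_r,
                          onset_lag_band=config.onset_lag_band,
                          onset_persistence=config.onset_persistence,
                          min_eeg_peak_hz=config.min_eeg_peak_hz,
                          rejected=rejected)
    manifest["timing_s"]["report"] = round(time.time() - t0, 3)
    manifest["timing_s"]["total"] = round(time.time() - t_start, 3)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        correlograms_to_frame(ccgs).to_csv(out / "correlograms.csv", index=False,
                                           float_format=_FLOAT_FMT)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report, ccgs, manifest


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__
    return {"nvcouple": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
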