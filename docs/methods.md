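# Methods

## The analysis problem

Anodal tDCS over one hemisphere perturbs cortical excitability; if
neurovascular coupling is intact, slow fluctuations of regional oxygen
saturation (rSO2) and of EEG band power should co-vary with a reproducible
temporal lag.  The pipeline estimates that lag from a randomized block
protocol: per trial, 5 s ramp-up, 50 s ON plateau, 5 s ramp-down, 60 s OFF,
repeated 15 times per hemisphere in random order (a 3600 s session).  Only
the middle 50 s of each OFF period is analyzed, so stimulation artifact and
ramp transients never enter the data.  All intervals are half-open
[start, end) in seconds from session start, which makes sample counts exact
at the 500 Hz (EEG) and 10 Hz (rSO2) rates used.

## Empirical Mode Decomposition

EMD is implemented from scratch by iterative sifting:

* **Extrema.** Strict interior local extrema; equal-valued plateaus count
  once at their center sample (left-center on even lengths).  This
  deterministic tie-break makes the decomposition bit-reproducible.
* **Envelopes.** Cubic splines through the maxima (upper) and minima
  (lower).  Ends are stabilized by mirroring the two extrema nearest each
  end about the end sample; on a 500-sample NIRS epoch edge effects are
  proportionally large and mirroring keeps the envelope swing bounded.
* **Stopping.** Sifting stops when the Cauchy criterion
  Σ(h_prev − h)² / Σ h_prev² falls below 0.2 (the classic default), or when
  the extrema and zero-crossing counts agree to within one for 3
  consecutive iterations (S-number rule), capped at 200 iterations (a cap
  hit logs a warning and returns the current candidate; it is not an
  error).  All three knobs are exposed.
* **Termination.** IMFs are extracted until the residual has fewer than two
  maxima or two minima.  Because the residual is formed by running
  subtraction, the completeness identity Σ IMF + residual = input holds to
  rounding precision by construction; the acceptance script measures
  ~3 × 10⁻¹⁶ relative error over 1000 random signals.
* **Spectral peak.** Peak-power frequency uses a single Hann-windowed
  periodogram (not Welch): on 50 s epochs this keeps the full 0.02 Hz
  resolution, which matters for distinguishing slow IMFs.  The original
  analysis did not state its sifting stop rule, boundary handling, or
  spectral estimator; the choices above are documented defaults of this
  package, not reconstructions.

## Per-trial coupling chain

EEG IMFs with spectral peak above 50 Hz are discarded (instrument and EMG
noise).  Each retained EEG IMF becomes a log10 mean-power series at 10 Hz:
non-overlapping 0.1 s windows of squared samples (50 samples per window).
Windowed squares rather than a Hilbert envelope were chosen because the
downsampling then needs no anti-alias filter; at the 10 Hz default carrier
one window spans exactly one oscillation period, so the power estimate is
smooth.  Window power is floored at 10⁻¹² times the epoch mean power so the
log stays finite on exact zeros.

Cross-correlation uses the biased normalized estimator (divisor fixed at N,
as standard econometric cross-correlation routines do) over lags ±20 s.
With x = NIRS IMF and y = EEG power series, a negative peak lag means NIRS
leads.  Values with |r| below n_std/√N (default n_std = 3; the white-noise
standard error of the correlation estimate, lag-independent) are zeroed; a
lag-dependent variant n_std/√(N−|k|) is available in config.  Under the
null, fewer than 0.1% of lag bins survive at N = 500 — conservative
relative to the nominal 0.27%, because the in-band correlation of
neighboring lags spreads survivors across few effective draws.

IMF pairing is configurable: `'index'` (default; NIRS IMF i against EEG
IMF i by original extraction index, matching timescale ranks across
modalities), `'rank'` (position within the retained list), or `'all'`
(every combination).  Which pairing the original analysis used is unknown;
parameter-recovery experiments here run `'all'` and let aggregation select
the coupled pair, which is robust to the IMF-index jitter EMD exhibits
between epochs.

## Aggregation and recovery

Two pair-selection rules coexist, and both are reported:

* **Significance count** (`dominant` field): the pair with at least one
  surviving correlation value in the greatest number of trials, ties toward
  the lower index.  This mirrors reporting a single most-common IMF, and it
  works when one pairing per index is computed.  In all-pairs mode it
  degenerates: any two slow components (NIRS Mayer wave against a slow EEG
  drift IMF) produce |r| above the white-noise bound in nearly every trial
  because slow series have few effective degrees of freedom.
* **Coherence** (default for `estimate`): the pair whose *trial-averaged*
  thresholded correlogram has the largest value inside the lag band of
  interest (default [−20, 0] s, the NIRS-leads hypothesis).  A genuinely
  coupled pair peaks at the same lag trial after trial and survives
  averaging; spuriously significant slow-on-slow pairs peak at random lags
  and cancel.  Candidate pairs must appear in ≥ 60% of analyzed trials and
  involve an oscillatory EEG IMF (spectral peak ≥ 1 Hz): the "band power"
  of a sub-delta drift component is just its squared waveform and carries
  no neural-envelope meaning.

The recovered lag is the in-band argmax of the mean thresholded correlogram
over the post-onset trials of the selected pair.  At the session level the
hemisphere with the stronger coherence score is reported — the protocol
queries one planted mechanism at two sites, and the better-measured site is
the session's estimate.

**Onset detection.**  A trial qualifies when its maximum thresholded
correlation inside the lag band reaches `min_r` (default: the significance
bound, i.e. any surviving value).  The onset is the earliest trial that
*itself qualifies* and from which at least `persistence` (default 0.8) of
the remaining trials qualify.  A pure tail-fraction rule was rejected: with
onset K and n trials the tail starting at K−1 already has fraction
(n−K+1)/(n−K+2), which exceeds 0.8 whenever more than a few trials follow,
so such a rule systematically fires one to two trials early on clean data.
Requiring the onset row itself to qualify restores exactness while the
persistence fraction still tolerates isolated weak trials.  Raising `min_r`
can only delay the detected onset (monotonicity, property-tested).
Onset indices are hemisphere-local (trial k of that hemisphere's 15), and
cumulative stimulation at onset counts ON plateaus only
(`k × 50 s`; 11 × 50 = 550 s), excluding ramps.

## Synthetic sessions

The generator emulates the study conditions with a known ground truth; per
hemisphere:

* a latent hemodynamic process s(t): unit-variance Gaussian noise
  band-limited to 0.03–0.08 Hz;
* rSO2 = 65% baseline + 1.5% · s(t) + Mayer (0.1 Hz, 0.4%), respiratory
  (0.25 Hz, 0.3%) and cardiac (1 Hz, 0.2%) sinusoids + white noise (0.3%),
  clipped to 40–90%;
* EEG center electrode = envelope-modulated 10 Hz carrier (10 µV) + 1/f
  background (3 µV rms) + white noise (2 µV).  From the first ON-plateau
  sample of the onset trial, the envelope is
  `max(0.05, 1 + gain · 0.6 · s(t − |lag|))`; before onset it is constant.
  The rSO2 slow component therefore leads the EEG power envelope by |lag|
  (lag −15 s, onset trial 11 by default).  Surround electrodes carry
  independent noise so the surround reference preserves the plant.  An
  `eeg_leads` mode (rSO2 = gamma-variate kernel applied to the neural slow
  process) is provided for generality.
* artifact trials receive 2–5 s bursts at ten times the carrier amplitude
  inside the analyzed OFF window of the designated trial's center
  electrode, exercising the rejection screen.

The single 10 Hz carrier (alpha/mu range) was chosen so the coupled
envelope concentrates in one low-index IMF; the noise amplitudes and the
65% baseline are free parameters — the study did not characterize its
patient's noise levels — set once to values typical of cerebral oximetry
and scalp EEG.  What the generator does **not** emulate: 1/f structure in
rSO2, nonstationary artifact morphology (real EMG/motion), electrode drift,
inter-channel EEG correlation, or any biophysical neurovascular model.
Passing recovery tests therefore demonstrates the pipeline's correctness
under its stated statistical model, not clinical validity on patient data.

EMD complicates recovery in an instructive way: the one-octave latent band
often splits across two neighboring NIRS IMFs, each a narrowband fragment
whose correlogram has period-spaced sidelobes, and the biased estimator's
triangular taper pushes peaks toward zero lag.  Coherence selection plus
post-onset averaging absorbs this: over 50 sessions with lags drawn from
[−18, −5] s and onsets from {5..12}, the session-level lag is recovered
within ±1 s in 98% of sessions (median absolute error 0.24 s) and the onset
exactly in 96% (seed 1; the acceptance script recomputes these).

## Numerical and interface choices

* Determinism: every stochastic step flows from one integer seed through
  independent spawned streams; identical (config, seed) gives bit-identical
  sessions, and the pipeline itself is deterministic.
* CSV time series round-trip exactly (17-significant-digit formatting,
  round-trip float parsing).  EDF export uses a minimal 16-bit writer
  (quantization ≤ range/2¹⁶); EDF reading goes through `mne`.  Analyses
  from EDF and CSV inputs agree to well within the quantization-induced
  perturbation of the (nonlinear) decomposition.
* Run configuration is fail-closed: unknown keys are rejected before any
  computation; the effective config, package versions, per-stage timing and
  per-trial errors are echoed into a manifest next to the outputs.
* Degenerate inputs: zero-variance series yield an all-zero flagged
  correlogram; all-zero IMFs report a 0 Hz peak; trials whose OFF window
  leaves the recording produce per-trial error records, never a global
  failure.
* The scalp helper fits a least-squares sphere to an idealized, synthetic
  10-10 layout (standard angular construction, 87 mm radius) rather than
  digitized human coordinates; it reports both chord and along-arc
  separations without adjudicating between them, since printed probe
  coordinates and nominal along-scalp separations are generally not
  consistent under the chord metric.

## Problem sizes

Validation uses 1000 random signals for decomposition exactness, 100 random
pairs for the estimator oracle, 1000 null pairs for false-positive control,
and 50 full sessions (30 trials each, 3600 s, two modalities) for parameter
recovery — about four minutes end to end on one CPU.

## Known limitations

Single-subject block designs give ~5–11 post-onset trials per hemisphere;
the onset rule cannot distinguish a true late onset from two consecutive
weak trials.  Lag recovery degrades for planted lags near the −20 s window
edge (shrinking overlap under the biased estimator).  No ensemble EMD
variants are provided, mode mixing between Mayer waves and the coupled slow
band is inherent at 50 s epochs, and no hemodynamic deconvolution or
system-identification modeling is attempted.
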