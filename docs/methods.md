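# Methods

This note documents the models, conventions and numerical choices behind
`gaitcmc`, in the order the pipeline applies them.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model and conditioning

A record is a channels × samples array at a single rate (default 2 kHz)
with per-channel roles: 10 monopolar EEG channels of the 10–20 set
(P3, P4, C3, Cz, C4, F7, F3, Fz, F4, F8), bilateral tibialis anterior
(TA) EMG, and four footswitch contact channels (heel and big toe of each
foot).

Conditioning (in `preprocess`):

1. **Unit-variance normalization** of EEG and EMG channels; the divisor is
   stored per channel so amplitude criteria stated in microvolts can still
   be applied afterwards.
2. **EEG band-pass** 0.5–70 Hz, 2nd-order Butterworth.  All filters in the
   package are applied forward–backward (zero phase): the analysis is
   event-locked, and causal filtering would shift latencies.  This is a
   deliberate convention of this implementation, as is every filter's
   exact application mode.
3. **Common average reference** over the monopolar EEG channels, then
   **bipolar sensorimotor derivations** C3−F3 (left hemisphere) and C4−F4
   (right hemisphere).  The difference of a nearby electrode pair
   suppresses far-field sources and common-mode artefacts.
4. **EMG rectification**: 20-Hz 4th-order Butterworth high-pass, then the
   modulus of the analytic (Hilbert) signal.  The rectified channel is
   used for EMG power and envelopes.
5. **EMG demodulation** for coherence: the rectified signal is
   mean-subtracted (the analytic phase of a strictly positive signal is
   degenerate) and divided by its instantaneous Hilbert amplitude, floored
   at 1e-8 × the median amplitude to avoid division blow-up on silent
   stretches.  The result is the cosine of the instantaneous phase: the
   periodic amplitude modulation of gait EMG — which would otherwise
   produce spurious coherence — is removed while phase structure is kept.
6. **Epoch rejection**: any epoch with an EEG sample exceeding 300 µV
   (configurable) is dropped before the trial count is fixed.  This
   automates, with a fixed threshold, what is often done by visual
   inspection; decomposition-based artefact removal (ICA and relatives) is
   deliberately out of scope and can be applied upstream by external
   tools before the record enters the pipeline.

## Gait events and temporal parameters

Heel strike is the upward crossing of the heel contact channel at 50% of
the channel range; toe-off is the downward crossing of the toe channel.
Crossing times are linearly interpolated between samples, and crossings
closer than 50 ms are merged (contact bounce).  The fractional threshold
makes detection invariant to amplitude scaling; threshold and debounce are
configurable because contact hardware varies.

Per gait cycle (consecutive same-foot heel strikes): stride time, step
time (to the next contralateral heel strike), stance (to the same-foot
toe-off), swing/single support (toe-off to next heel strike), and double
support measured per step as the interval from the contralateral heel
strike to the same-foot toe-off (~0.14–0.16 s per step for healthy gait).
Stance + swing equals stride identically, by construction of the phase
definitions.  Means and SDs pool both feet; a validity mask supports
excluding intervals such as turning sections.  A record with fewer than
100 valid heel strikes on either foot is rejected as a footswitch failure.

## Time–frequency decomposition

Epochs span −800 to +200 ms around heel strike (1 s, t = 0 at a fixed
sample index), at most 220 per record; heel strike of the analysed side is
the reference (left TA pairs with C4−F4, right TA with C3−F3).

The STFT uses a 375-ms periodic Hann window at 25-ms hops, giving the
frequency grid k/0.375 s = k·2.667 Hz.  Windows are always **fully
supported by real samples — no zero padding** — and each bin is stamped at
its window centre.  On a bare 1-s epoch this yields 26 window positions
with centres −612.5 … +12.5 ms.  Because the double-support analysis
window (0–125 ms) then contains a single bin, epoching accepts a
`margin_s` option that extracts ±187.5 ms of *additional real record
samples* around the nominal epoch; window centres are then restricted to
the nominal span, tiling −800 … +175 ms at 25 ms and covering 0–125 ms
with six bins.  The pipeline default is `margin_s = 0.1875`; `margin_s = 0`
reproduces the bare-epoch grid.  Epochs whose extended window leaves the
record are dropped.

Band membership and window membership are decided by bin centres falling
inside closed intervals.  On the 2.667-Hz grid the five bands resolve to
centres: theta {5.33}, alpha {8.0, 10.67}, low beta {13.33, 16.0, 18.67},
high beta {21.33, 24.0, 26.67, 29.33}, gamma {32.0 … 42.67} Hz.  The low
beta band is defined as 13–20 Hz; band edges are configurable.

## Spectral measures and the parametric null

EEG power is expressed per trial as percent change from the per-frequency
mean over the epoch (phasic modulation only; tonic level cancels), then
trial-averaged.  EMG power is the natural log of the trial-mean power of
the rectified EMG.  Inter-trial coherence (amplitude-weighted estimator;
a phase-only variant is available) and corticomuscular coherence follow
the standard magnitude-squared forms over trials.

For L independent segments the null distribution of magnitude-squared
coherence gives `P(C > c) = (1 − c)^(L−1)`; p-values are computed in log
space (`(L−1)·log1p(−C)`) and mapped through the inverse standard normal,
capped at |z| = 8.2 where the double-precision quantile saturates.  When
amplitude rejection leaves fewer than 220 epochs, the actual L propagates
into p-values and thresholds.  Coherence maps are masked by zeroing bins
below `C_thr = 1 − alpha^(1/(L−1))` (≈0.0136 at L = 220, alpha = 0.05);
the threshold rises as L falls.

Because consecutive STFT windows overlap by 350 of 375 ms, neighbouring
time bins of one trial set are strongly correlated; Monte-Carlo
calibration of the null therefore pools many *independent* trial-set
pairs (default 100, ≈94k bins) rather than relying on the raw bin count.

## EMG envelopes

Per-trial rectified EMG is smoothed with a zero-phase 2nd-order 45-Hz
low-pass, trial-averaged, and normalized so that the peak within the gait
cycle is 100%.  The peak is taken on the trial-averaged envelope over the
full available epoch span (margin included, approximating the full
stride); per-trial normalization would inflate noise.  Summary amplitudes
are means over the foot-lift (−0.40…−0.25 s) and foot-drop (0.04…0.08 s)
windows, and can be correlated with per-record coherence summaries
(Pearson by default, Spearman optional).

## Group statistics

The pipeline exports a tidy table (record × side × condition × measure ×
band) intended for repeated-measures mixed-model analysis in dedicated
statistics software; re-implementing mixed models is out of scope.  For
self-contained screening it includes a Welch two-sample test per cell
with Benjamini–Hochberg adjustment across the 25-cell grid (step-up,
implemented in-package and cross-checked against statsmodels in the test
suite) and Cohen's d_s with the pooled-SD denominator (n_a + n_b − 2).
d_s is known to be inflated in small samples (Hedges' correction is not
applied, matching common practice in this literature); the test suite
quantifies the inflation at n = 20 per group.

## Synthetic records

The generator emulates the statistical structure the analysis assumes —
not biomechanics or volume conduction:

- **Timeline**: left stride times i.i.d. N(1.10 s, 0.020 s) by default;
  per-cycle stance and double support scale proportionally to the realized
  stride so phase fractions are preserved; the contralateral heel strike
  falls stance − double-support after the ipsilateral one.  Group presets
  (young / old / pd) use stride 1.10/1.09/1.06 s, stance 0.689/0.696/0.674 s,
  swing 0.404/0.381/0.382 s, double support 0.146/0.156/0.160 s.
- **Footswitches**: clean 0/1 contact with a 5-ms linear rise centred on
  the true event time (so the 50% crossing recovers the event exactly);
  the heel opens mid-stance, the toe closes at foot-flat and opens at
  toe-off.
- **EEG**: per-channel 1/f-shaped noise (exponent 1.0, spectral shaping of
  white noise floored below 0.5 Hz), 15 µV SD.  Optional gait-locked
  artefact transients (> a configured amplitude, default 400 µV) on a
  random fraction of cycles emulate movement artefacts.
- **EMG**: broadband 20–450 Hz noise multiplied by a deterministic
  cycle-locked envelope — an early-swing burst (centre −325 ms) and a
  double-peaked burst around heel strike (t = 0 and +60 ms), Gaussian
  shapes with group-dependent gains and a small baseline.
- **Coupling**: one shared band-limited Gaussian process per band and
  side, gated to the double-support window by a raised-cosine taper.  A
  coupling strength γ ∈ [0, 1] adds γ × 8 µV of the gated drive to the
  contralateral sensorimotor channel (C4 for left TA) and modulates the
  EMG envelope by (1 + 0.5 γ × gated drive).  Both gains were fixed from
  first-principles SNR considerations (drive vs 1/f background power in
  the beta band, L = 220) so that γ = 0.8 produces clearly
  supra-threshold coherence while per-bin coherence stays below the z-cap,
  and γ = 0 yields exact independence.  The old/pd presets use γ = 0.53
  vs 0.8 for young, i.e. the ≈0.66 ratio of reported group means for this
  measure.

With γ = 0, EEG and EMG are independent by construction, so the z-scored
coherence over bins is the package's strongest self-check: mean ≈ 0,
SD ≈ 1, and ≈5% of bins above the 95% mask.  What passing these checks
does **not** show: robustness to real movement artefacts beyond simple
amplitude transients, volume-conducted crosstalk, electrode impedance
drift, or non-Gaussian EMG statistics; the generator is a calibration
instrument, not a forward model of walking humans.

## Problem sizes and determinism

All randomness flows from integer seeds through `numpy` generators;
records are bit-identical under a fixed config, and the pipeline output
tables are deterministic end to end.  The test suite uses 40–120 s records
(≈35–110 epochs) for most properties, a 295-s record for the 220-epoch
segmentation contract, a 600-s record for gait-parameter recovery, a
5 × 20 coupling grid of 120-s records for monotonic coupling recovery
(Spearman over seed-averaged level means), and 100 independent L = 220
trial-set pairs for null calibration.  These sizes were chosen so each
statistical check has comfortable Monte-Carlo margin while the whole
suite stays desk-scale.

## Known limitations

- The double-support average with `margin_s = 0` rests on one STFT bin;
  use the default margin for window-resolved summaries.
- The parametric null assumes independent trials; epochs that overlap in
  the record (possible when margins exceed the stride time) violate this
  mildly, so null calibration uses non-overlapping epoch sets.
- EDF files are read (via `mne`) but not written; the native container is
  a TSV sample matrix with a JSON sidecar.
- Walking speed is metadata passed through to the gait table, never
  estimated from signals.
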