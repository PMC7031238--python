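# gaitcmc

Gait-cycle-resolved EEG/EMG spectral analysis: corticomuscular coherence,
inter-trial coherence and event-related power during walking.

## The problem

During walking, the sensorimotor cortex and the spinal motor neuron pools
driving the ankle dorsiflexors (tibialis anterior, TA) exchange oscillatory
activity that is visible as *corticomuscular coherence* (CMC) between scalp
EEG and surface EMG.  This coupling is concentrated in the **double-support
phase** of the gait cycle (the ~125 ms after heel strike when both feet are
on the ground) and in the **low beta band (13–20 Hz)**, and it weakens with
age and in neurodegenerative disease.  Quantifying it from ambulatory
recordings requires a chain of well-defined steps — footswitch event
detection, artefact-aware conditioning, heel-strike-locked time–frequency
decomposition, parametric significance testing, and multiple-comparison
control — each of which this package implements as a tested, reusable
operation.

`gaitcmc` is aimed at movement-neuroscience researchers who record
multichannel EEG (10–20 montage), bilateral TA EMG and footswitches at
2 kHz during treadmill or overground walking, and want the full pipeline
from raw channels to tidy per-record outcome tables.  Because raw human
recordings of this kind are rarely shareable, the package also ships a
first-class **synthetic-record generator** with known ground truth
(stride timing, EMG burst shape, injected cortex–muscle coupling) so every
stage of the analysis is verifiable end to end.

## The measures

Signals are cut into up to *L* = 220 one-second epochs spanning −800 to
+200 ms around heel strike and decomposed with a short-time Fourier
transform (375-ms Hann window, 25-ms hop, Δf = 2.67 Hz).  With single-trial
coefficients X_k(t, f) and Y_k(t, f) for an EEG derivation and the
contralateral EMG:

- **Event-related EEG power** — percent change from the per-frequency mean
  over the epoch, computed per trial, then trial-averaged:
  `P%(t,f) = 100 · (|X_k|² − ⟨|X_k|²⟩_t) / ⟨|X_k|²⟩_t`.
- **Event-related EMG power** — `log ⟨|Y_k|²⟩_k` of the rectified EMG.
- **Inter-trial coherence** — `ITC(t,f) = |Σ_k X_k|² / (L Σ_k |X_k|²)`,
  1 for identical trials, ≈1/L under independence.
- **Corticomuscular coherence** —
  `C(t,f) = |Σ_k X_k Y_k*|² / (Σ_k |X_k|² · Σ_k |Y_k|²)`.
- **z-scoring** — under the null of independent signals
  `P(C > c) = (1 − c)^(L−1)`, so `z = Φ⁻¹(1 − (1−C)^(L−1))` is standard
  normal when the signals are unrelated; coherence maps are masked at the
  95% confidence threshold `C_thr = 1 − 0.05^(1/(L−1))`.

Band summaries average each map over the double-support window
(0–125 ms) in five bands — theta 4–7, alpha 8–12, low beta 13–20, high
beta 21–30, gamma 31–45 Hz — yielding the 5 × 5 outcome grid whose
group comparisons are controlled with the Benjamini–Hochberg FDR
procedure (Cohen's d_s effect sizes included).  EMG is high-passed at
20 Hz, full-wave rectified via the Hilbert envelope, and *demodulated*
(unit instantaneous amplitude, phase preserved) before coherence, so
periodic amplitude modulation cannot masquerade as coupling.

## Worked example

```python
import pandas as pd
from gaitcmc import config_for_group, generate_record
from gaitcmc.pipeline import AnalysisConfig, analyze_record

cfg = config_for_group("young", duration_s=300.0, seed=7)   # coupled low-beta drive
record, truth = generate_record(cfg)                        # 10 EEG + 2 EMG + 4 footswitch
result = analyze_record(record, "young-07", "young", "treadmill", AnalysisConfig())

print(result.n_epochs)
print(result.gait.as_dict())
df = pd.DataFrame(result.band_rows)
print(df.query("measure == 'cmc_z' and side == 'left'").set_index("band")["value"].round(2))
```

prints (abridged):

```
epochs per side: {'left': 220, 'right': 220}
{'stride_time_s': 1.097, 'stride_time_sd_s': 0.016, 'step_time_s': 0.548,
 'stance_s': 0.687, 'swing_single_support_s': 0.41, 'double_support_s': 0.139, ...}
left-side CMC z during double support:
theta        1.03
alpha        0.46
low_beta     5.15
high_beta    2.01
gamma        0.55
```

The gait parameters recover the configured stride structure (1.10 s
strides, 0.69 s stance, 0.14 s double support per step), and the injected
low-beta cortex–muscle coupling appears exactly where it should: a clearly
significant CMC z in the low beta band during double support (null bins
are ~N(0,1)), with modest spectral leakage into high beta and nothing
elsewhere.  The same record's TA envelope shows the early-swing burst
(foot lift ≈ 39% of the cycle peak) and the double-peaked burst around
heel strike (foot drop ≈ 80%).

A shell session does the same end to end:

```sh
gaitcmc simulate --out sim --group young --group old --n 5 --duration 300 --seed 1
gaitcmc analyze sim/young-001 sim/old-001 --out results
gaitcmc report results/outcomes.tsv --out results
```

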