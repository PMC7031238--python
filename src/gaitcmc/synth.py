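"""Synthetic ambulatory EEG/EMG/footswitch records with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be verified without human recordings:

* a gait timeline with Gaussian stride-time jitter (defaults: 1.10 s mean,
  0.020 s SD) and per-cycle phase durations jittered proportionally so the
  phase fractions of the cycle are preserved;
* tibialis anterior EMG as broadband noise amplitude-modulated by a
  cycle-locked envelope with a burst during early swing and a double-peaked
  burst around heel strike (t = 0 and t = +60 ms);
* 10-channel EEG (10-20 montage) as 1/f-shaped background noise;
* cortex-muscle coupling as a shared band-limited Gaussian process, gated
  to the double-support phase by a raised-cosine taper, added to the
  sensorimotor EEG channel contralateral to the muscle and multiplied into
  the EMG envelope of that muscle.  Coupling strength in [0, 1] scales both
  projections, producing genuine, tunable cross-spectral coherence;
* footswitch channels as clean 0/1 contact pulses with a 5-ms rise centred
  on the true event time;
* optional gait-locked movement artefacts exceeding a configured amplitude
  on a random subset of cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventSeries, FootEvents, FEET
from .noise import bandlimited_noise, pink_noise
from .records import Channel, SignalRecord, EEG_1020_LABELS
from .spectral import BANDS

GROUPS = ("young", "old", "pd")

#: Which sensorimotor monopolar channel carries the drive coupled to each
#: TA muscle (opposite hemisphere: left TA <-> right cortex C4, and v.v.).
CONTRALATERAL_EEG = {"left": "C4", "right": "C3"}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic gait record.

    Durations are in seconds, amplitudes in microvolts.  ``coupling`` maps
    a band name from :data:`BANDS` to a strength in [0, 1] that is applied
    inside ``coupling_window_s`` (relative to each heel strike; default the
    double-support window 0-125 ms).  ``emg_burst_times_s`` lists
    ``(center, width)`` pairs of the cycle-locked envelope bursts relative
    to heel strike, with per-burst gains in ``emg_burst_gains`` relative to
    the tallest burst.
    """

    sample_rate_hz: float = 2000.0
    duration_s: float = 300.0
    stride_mean_s: float = 1.10
    stride_sd_s: float = 0.020
    stance_s: float = 0.69
    swing_s: float = 0.41
    double_support_s: float = 0.14
    coupling: dict = field(default_factory=lambda: {"low_beta": 0.0})
    coupling_window_s: tuple = (0.0, 0.125)
    emg_burst_times_s: tuple = ((-0.325, 0.050), (0.0, 0.018), (0.060, 0.022))
    emg_burst_gains: tuple = (0.5, 1.0, 0.9)
    emg_baseline: float = 0.08
    eeg_background_uv: float = 15.0
    eeg_drive_gain_uv: float = 8.0
    emg_scale_uv: float = 150.0
    emg_mod_depth: float = 0.5
    pink_exponent: float = 1.0
    artefact_amplitude_uv: float = 400.0
    artefact_rate: float = 0.0
    group_label: str = "young"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sample_rate_hz and duration_s must be positive")
        for name in ("stride_mean_s", "stance_s", "swing_s", "double_support_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stride_sd_s < 0:
            raise ValueError("stride_sd_s must be non-negative")
        if abs(self.stance_s + self.swing_s - self.stride_mean_s) > 0.015:
            raise ValueError(
                "stance_s + swing_s must equal stride_mean_s within 15 ms "
                f"(got {self.stance_s + self.swing_s:.3f} vs {self.stride_mean_s:.3f})"
            )
        if self.double_support_s >= self.stance_s:
            raise ValueError("double_support_s must be smaller than stance_s")
        for band, strength in self.coupling.items():
            if band not in BANDS:
                raise ValueError(f"unknown coupling band {band!r}")
            if not 0.0 <= strength <= 1.0:
                raise ValueError(f"coupling strength for {band} must be in [0, 1]")
        if len(self.emg_burst_times_s) != len(self.emg_burst_gains):
            raise ValueError("emg_burst_times_s and emg_burst_gains length mismatch")
        if self.artefact_amplitude_uv < 0 or not 0.0 <= self.artefact_rate <= 1.0:
            raise ValueError("artefact_amplitude_uv >= 0 and artefact_rate in [0, 1] required")
        if self.group_label not in GROUPS:
            raise ValueError(f"group_label must be one of {GROUPS}")


#: Group presets: temporal gait parameters follow the reported group means
#: (young / old / PD); the low-beta coupling deficit of the two older
#: groups uses the ratio of their reported low-beta CMC z to the young
#: group's (~0.66), and the early-swing EMG burst gains follow the reported
#: foot-lift amplitudes (as fractions of the heel-strike peak).
GROUP_PRESETS: dict[str, dict] = {
    "young": dict(
        stride_mean_s=1.10, stride_sd_s=0.020, stance_s=0.689, swing_s=0.404,
        double_support_s=0.146, emg_burst_gains=(0.48, 1.0, 0.90),
        coupling={"low_beta": 0.8},
    ),
    "old": dict(
        stride_mean_s=1.09, stride_sd_s=0.019, stance_s=0.696, swing_s=0.381,
        double_support_s=0.156, emg_burst_gains=(0.67, 1.0, 0.88),
        coupling={"low_beta": 0.53},
    ),
    "pd": dict(
        stride_mean_s=1.06, stride_sd_s=0.021, stance_s=0.674, swing_s=0.382,
        double_support_s=0.160, emg_burst_gains=(0.62, 1.0, 0.75),
        coupling={"low_beta": 0.53},
    ),
}


def config_for_group(group: str, **overrides) -> SynthConfig:
    """A :class:`SynthConfig` pre-filled with the preset for one study group."""
    if group not in GROUP_PRESETS:
        raise ValueError(f"unknown group {group!r}")
    params = dict(GROUP_PRESETS[group], group_label=group)
    params.update(overrides)
    return SynthConfig(**params)


@dataclass
class GroundTruth:
    """Everything injected into a synthetic record, for recovery tests."""

    event_series: EventSeries
    coupling: dict
    coupling_window_s: tuple
    artefact_cycles: dict
    config: SynthConfig


# ---------------------------------------------------------------------------
# timeline
# ---------------------------------------------------------------------------


def generate_gait_timeline(config: SynthConfig, start_s: float = 1.5) -> EventSeries:
    """Generate alternating left/right heel-strike and toe-off times.

    Left stride times are drawn i.i.d. from N(stride_mean_s, stride_sd_s);
    per-cycle stance and double-support durations are scaled proportionally
    to the realized stride so the phase fractions are preserved.  The
    contralateral (right) heel strike falls ``stance - double_support``
    after the left one, which makes each per-step double support equal the
    configured value up to the stride jitter.
    """
    c = config
    if c.duration_s < start_s + 2 * c.stride_mean_s:
        raise ValueError(
            f"duration_s={c.duration_s} too short for one full gait cycle "
            f"(need >= {start_s + 2 * c.stride_mean_s:.2f} s)"
        )
    rng = np.random.default_rng([c.seed, 0])
    stop = c.duration_s - 0.5
    strides = []
    t = start_s
    while t < stop:
        T = c.stride_mean_s if c.stride_sd_s == 0 else max(
            rng.normal(c.stride_mean_s, c.stride_sd_s), 0.5 * c.stride_mean_s
        )
        strides.append(T)
        t += T
    strides = np.asarray(strides[:-1]) if t >= stop else np.asarray(strides)
    if strides.size < 2:
        raise ValueError("duration too short for two strides")
    lhs = start_s + np.concatenate([[0.0], np.cumsum(strides)])
    stance_frac = c.stance_s / c.stride_mean_s
    step_frac = (c.stance_s - c.double_support_s) / c.stride_mean_s
    lto = lhs[:-1] + stance_frac * strides
    rhs = lhs[:-1] + step_frac * strides
    r_strides = np.diff(rhs)
    rto = rhs[:-1] + stance_frac * r_strides
    # keep only events inside the record
    def _clip(x):
        return x[(x > 0) & (x < c.duration_s)]
    return EventSeries(
        FootEvents(_clip(lhs), _clip(lto)),
        FootEvents(_clip(rhs), _clip(rto)),
    )


def _heel_strikes(timeline: EventSeries, side: str) -> np.ndarray:
    return timeline.foot(side).heel_strikes


# ---------------------------------------------------------------------------
# shared drives and gates
# ---------------------------------------------------------------------------


def make_drives(config: SynthConfig, n: int, rng: np.random.Generator) -> dict:
    """One unit-variance band-limited process per (coupling band, side)."""
    drives: dict[str, dict[str, np.ndarray]] = {}
    for band in config.coupling:
        lo, hi = BANDS[band]
        drives[band] = {
            side: bandlimited_noise(n, config.sample_rate_hz, lo, hi, rng) for side in FEET
        }
    return drives


def _gate(timeline: EventSeries, side: str, config: SynthConfig, n: int) -> np.ndarray:
    """Raised-cosine taper over the coupling window after each heel strike."""
    fs = config.sample_rate_hz
    w0, w1 = config.coupling_window_s
    width = int(round((w1 - w0) * fs))
    taper = np.hanning(width)
    gate = np.zeros(n)
    for hs in _heel_strikes(timeline, side):
        i0 = int(round((hs + w0) * fs))
        if i0 < 0 or i0 + width > n:
            continue
        gate[i0 : i0 + width] = np.maximum(gate[i0 : i0 + width], taper)
    return gate


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def cycle_envelope(timeline: EventSeries, side: str, config: SynthConfig,
                   n: int) -> np.ndarray:
    """Deterministic cycle-locked EMG envelope (baseline + Gaussian bursts)."""
    fs = config.sample_rate_hz
    t = np.arange(n) / fs
    env = np.full(n, config.emg_baseline)
    half = 5.0  # bursts only influence +-5 sigma around their centre
    for hs in _heel_strikes(timeline, side):
        for (center, width), gain in zip(config.emg_burst_times_s, config.emg_burst_gains):
            c = hs + center
            i0 = max(int((c - half * width) * fs), 0)
            i1 = min(int((c + half * width) * fs) + 1, n)
            if i0 >= i1:
                continue
            env[i0:i1] += gain * np.exp(-0.5 * ((t[i0:i1] - c) / width) ** 2)
    return env


def generate_emg(
    timeline: EventSeries,
    config: SynthConfig,
    drives: dict,
    side: str = "left",
    rng: np.random.Generator | None = None,
    n: int | None = None,
) -> np.ndarray:
    """Single-channel TA EMG for one side.

    Broadband (20-450 Hz) noise is amplitude-modulated by the cycle-locked
    envelope; inside the double-support window the envelope is additionally
    modulated by the shared band-limited drive, scaled by the coupling
    strength.  With zero coupling the EMG is independent of the drive.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 10 + FEET.index(side)])
    fs = config.sample_rate_hz
    if n is None:
        n = int(round(config.duration_s * fs))
    carrier = bandlimited_noise(n, fs, 20.0, min(450.0, 0.45 * fs), rng)
    env = cycle_envelope(timeline, side, config, n)
    mod = np.ones(n)
    if any(s > 0 for s in config.coupling.values()):
        gate = _gate(timeline, side, config, n)
        for band, strength in config.coupling.items():
            if strength > 0:
                mod += config.emg_mod_depth * strength * gate * drives[band][side]
    np.clip(mod, 0.0, None, out=mod)
    emg = config.emg_scale_uv * env * mod * carrier
    emg += 1.0 * rng.standard_normal(n)  # instrumentation noise floor
    return emg


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


def generate_eeg(
    timeline: EventSeries,
    config: SynthConfig,
    drives: dict,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    channel_labels: tuple = EEG_1020_LABELS,
) -> np.ndarray:
    """10-channel EEG: 1/f background plus gated drive on C3/C4.

    The drive coupled to each TA muscle is projected onto the contralateral
    sensorimotor channel (left TA <-> C4, right TA <-> C3) inside the
    coupling window, so the bipolar derivations C4-F4 / C3-F3 carry it.
    Optional gait-locked artefact transients exceeding
    ``artefact_amplitude_uv`` are added on a random subset of cycles.
    """
    for lab in channel_labels:
        if lab not in EEG_1020_LABELS:
            raise ValueError(f"unknown 10-20 channel label {lab!r}")
    if rng is None:
        rng = np.random.default_rng([config.seed, 20])
    fs = config.sample_rate_hz
    if n is None:
        n = int(round(config.duration_s * fs))
    eeg = np.empty((len(channel_labels), n))
    for i in range(len(channel_labels)):
        eeg[i] = config.eeg_background_uv * pink_noise(n, fs, config.pink_exponent, rng)
    if any(s > 0 for s in config.coupling.values()):
        for side in FEET:
            target = CONTRALATERAL_EEG[side]
            if target not in channel_labels:
                continue
            gate = _gate(timeline, side, config, n)
            row = channel_labels.index(target)
            for band, strength in config.coupling.items():
                if strength > 0:
                    eeg[row] += config.eeg_drive_gain_uv * strength * gate * drives[band][side]
    return eeg


def _inject_artefacts(
    eeg: np.ndarray, timeline: EventSeries, config: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Add gait-locked biphasic transients on a random subset of left cycles."""
    fs = config.sample_rate_hz
    hs = _heel_strikes(timeline, "left")
    n_cycles = hs.size
    n_bad = int(round(config.artefact_rate * n_cycles))
    if n_bad == 0:
        return np.empty(0, dtype=int)
    bad = np.sort(rng.choice(n_cycles, size=n_bad, replace=False))
    width = int(0.030 * fs)
    t = np.arange(width) / fs
    shape = np.sin(2 * np.pi * t / (width / fs)) * np.hanning(width)
    for ci in bad:
        i0 = int(round((hs[ci] + 0.02) * fs))
        if i0 + width > eeg.shape[1]:
            continue
        gains = config.artefact_amplitude_uv * rng.uniform(1.15, 1.6, size=eeg.shape[0])
        eeg[:, i0 : i0 + width] += gains[:, None] * shape[None, :]
    return bad


# ---------------------------------------------------------------------------
# footswitches and assembly
# ---------------------------------------------------------------------------


def _contact_trace(n: int, fs: float, closures, rise_s: float = 0.005) -> np.ndarray:
    """0/1 contact with linear rise/fall of ``rise_s`` centred on event times."""
    h = rise_s / 2.0
    xs, ys = [0.0], [0.0]
    for t_close, t_open in closures:
        xs += [t_close - h, t_close + h, t_open - h, t_open + h]
        ys += [0.0, 1.0, 1.0, 0.0]
    xs.append(n / fs)
    ys.append(0.0)
    t = np.arange(n) / fs
    return np.interp(t, xs, ys)


def generate_footswitches(timeline: EventSeries, config: SynthConfig, n: int) -> dict:
    """Four contact traces (side x heel/toe) from the timeline.

    The heel switch closes at heel strike and opens during mid-stance; the
    toe switch closes at foot-flat and opens at toe-off, so heel strike is
    the rising heel edge and toe-off the falling toe edge.
    """
    fs = config.sample_rate_hz
    out = {}
    for side in FEET:
        fe = timeline.foot(side)
        hs, to = fe.heel_strikes, fe.toe_offs
        heel, toe = [], []
        for h in hs:
            nxt = to[to > h]
            if nxt.size == 0:
                continue
            stance = nxt[0] - h
            heel.append((h, h + 0.6 * stance))
            toe.append((h + 0.15 * stance, nxt[0]))
        out[(side, "heel")] = _contact_trace(n, fs, heel)
        out[(side, "toe")] = _contact_trace(n, fs, toe)
    return out


FOOTSWITCH_LABELS = {
    ("left", "heel"): "LHEEL",
    ("left", "toe"): "LTOE",
    ("right", "heel"): "RHEEL",
    ("right", "toe"): "RTOE",
}


def generate_record(config: SynthConfig) -> tuple[SignalRecord, GroundTruth]:
    """Assemble a full synthetic record: 10 EEG + 2 EMG + 4 footswitch channels.

    Deterministic under a fixed config: identical seed and parameters give
    bit-identical arrays.
    """
    fs = config.sample_rate_hz
    n = int(round(config.duration_s * fs))
    timeline = generate_gait_timeline(config)
    drive_rng = np.random.default_rng([config.seed, 1])
    drives = make_drives(config, n, drive_rng)
    eeg = generate_eeg(timeline, config, drives, n=n)
    art_rng = np.random.default_rng([config.seed, 30])
    artefact_cycles = _inject_artefacts(eeg, timeline, config, art_rng)
    channels = [Channel(lab, "eeg", "uV") for lab in EEG_1020_LABELS]
    rows = [eeg]
    for side in FEET:
        emg = generate_emg(timeline, config, drives, side=side, n=n)
        rows.append(emg[None, :])
        channels.append(Channel(f"TA_{side}", "emg", "uV", {"side": side, "muscle": "TA"}))
    switches = generate_footswitches(timeline, config, n)
    for key, label in FOOTSWITCH_LABELS.items():
        rows.append(switches[key][None, :])
        channels.append(Channel(label, "footswitch", "", {"side": key[0], "part": key[1]}))
    record = SignalRecord(
        np.vstack(rows),
        fs,
        channels,
        history=[f"synthetic record (group={config.group_label}, seed={config.seed})"],
        meta={"group": config.group_label, "seed": config.seed, "synthetic": True},
    )
    truth = GroundTruth(
        event_series=timeline,
        coupling=dict(config.coupling),
        coupling_window_s=config.coupling_window_s,
        artefact_cycles={"left": np.asarray(artefact_cycles, dtype=int)},
        config=config,
    )
    return record, truth
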