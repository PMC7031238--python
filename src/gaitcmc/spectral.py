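"""Heel-strike-locked epoching, STFT and event-related spectral measures.

Signals are segmented into up to 220 one-second epochs spanning -800 to
+200 ms around heel strike and decomposed with a short-time Fourier
transform (375-ms Hann window, 25-ms hop, frequency resolution
1/0.375 s = 2.667 Hz).  From the single-trial complex coefficients
``X_k(t, f)`` five measures are derived:

* event-related EEG power, the percent change from the per-frequency mean
  power over the analysis interval, computed per trial before averaging;
* event-related EMG power, the natural log of the trial-mean power;
* inter-trial coherence  ``ITC = |sum_k X_k|^2 / (L sum_k |X_k|^2)``;
* corticomuscular coherence
  ``C = |sum_k X_k Y_k*|^2 / (sum_k |X_k|^2 sum_k |Y_k|^2)``;
* their z-scores via the parametric null of magnitude-squared coherence
  over L segments, ``p = (1 - C)^(L-1)``, mapped through the standard
  normal quantile, so z ~ N(0, 1) when the signals are independent.

Coherence maps can be masked at the 95% confidence level using the
parametric threshold ``C_thr = 1 - alpha^(1/(L-1))`` and summarised as
band x window averages (the unit of statistical comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import norm

from .events import EventSeries
from .records import Channel, SignalRecord

#: Frequency bands (Hz, closed intervals on bin centres).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (21.0, 30.0),
    "gamma": (31.0, 45.0),
}

#: Double-support analysis window, seconds relative to heel strike.
DOUBLE_SUPPORT_WINDOW = (0.0, 0.125)

#: Nominal epoch span relative to heel strike, seconds (half-open).
EPOCH_SPAN = (-0.8, 0.2)

#: Default trial cap per record and condition.
MAX_EPOCHS = 220

#: STFT window length and hop, seconds.
STFT_WINDOW_S = 0.375
STFT_HOP_S = 0.025

#: |z| cap for the coherence z-transform (double-precision quantile limit).
Z_CAP = 8.2

_TOL = 1e-9  # closed-interval tolerance for grid selection


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Heel-strike-aligned trial x channel x time array.

    ``data`` may carry a symmetric margin of extra real samples beyond the
    nominal span (used so STFT windows centred near the span edges are
    computable without zero padding).  ``t0_index`` is the sample index of
    heel strike (t = 0), identical across trials.
    """

    data: np.ndarray  # (L, n_channels, n_samples)
    sample_rate_hz: float
    channels: list[Channel]
    t0_index: int
    span_s: tuple = EPOCH_SPAN
    margin_s: float = 0.0
    heel_strike_times: np.ndarray = None
    reference_foot: str = "left"
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, time)")
        if self.heel_strike_times is None:
            self.heel_strike_times = np.full(self.data.shape[0], np.nan)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time of each sample relative to heel strike (seconds)."""
        return (np.arange(self.data.shape[2]) - self.t0_index) / self.sample_rate_hz

    def index(self, label: str) -> int:
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"channel {label!r} not in epochs; available: "
                       f"{[c.label for c in self.channels]}")

    def channel_data(self, label: str) -> np.ndarray:
        """(L, time) array of one channel."""
        return self.data[:, self.index(label), :]

    def select(self, mask_or_indices) -> "EpochSet":
        return EpochSet(
            self.data[mask_or_indices],
            self.sample_rate_hz,
            [c.copy() for c in self.channels],
            self.t0_index,
            self.span_s,
            self.margin_s,
            np.asarray(self.heel_strike_times)[mask_or_indices],
            self.reference_foot,
            list(self.history),
        )

    def truncate(self, max_epochs: int) -> "EpochSet":
        if self.n_epochs <= max_epochs:
            return self
        out = self.select(np.arange(max_epochs))
        out.history.append(f"truncate(first {max_epochs} epochs)")
        return out


@dataclass
class Spectrogram:
    """Single-trial complex STFT coefficients: (trials, freqs, time bins)."""

    coef: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # window-centre times relative to heel strike
    window: str
    sample_rate_hz: float
    channel: str = ""

    @property
    def n_trials(self) -> int:
        return self.coef.shape[0]

    def power(self) -> np.ndarray:
        return np.abs(self.coef) ** 2

    def _check_grid(self, other: "Spectrogram") -> None:
        if self.coef.shape != other.coef.shape or not (
            np.allclose(self.freqs, other.freqs) and np.allclose(self.times, other.times)
        ):
            raise ValueError("spectrogram grids do not match")


@dataclass
class TimeFreqMap:
    """Frequency x time values of one spectral measure."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    measure: str
    n_trials: int
    mask: np.ndarray = None  # True where the value survived thresholding

    def band_freq_indices(self, band) -> np.ndarray:
        lo, hi = BANDS[band] if isinstance(band, str) else band
        return np.flatnonzero((self.freqs >= lo - _TOL) & (self.freqs <= hi + _TOL))

    def window_time_indices(self, window) -> np.ndarray:
        a, b = window
        return np.flatnonzero((self.times >= a - _TOL) & (self.times <= b + _TOL))


@dataclass
class BandSummary:
    """Scalar summary of one measure over one band x analysis window."""

    measure: str
    band: str
    window: tuple
    value: float
    n_trials: int

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "band": self.band,
            "window_start_s": self.window[0],
            "window_stop_s": self.window[1],
            "value": self.value,
            "L": self.n_trials,
        }


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


def epoch_signals(
    record: SignalRecord,
    events: EventSeries,
    reference_foot: str = "left",
    max_epochs: int | None = MAX_EPOCHS,
    span_s: tuple = EPOCH_SPAN,
    margin_s: float = 0.0,
    invalid_intervals=None,
    amplitude_threshold_uv: float | None = None,
) -> EpochSet:
    """Cut heel-strike-locked epochs from a conditioned record.

    One epoch per valid heel strike of ``reference_foot``, spanning
    ``span_s`` (default [-0.8, +0.2) s) plus ``margin_s`` of extra real
    samples on each side.  Epochs whose extended window leaves the record,
    overlap an invalid interval, or (if ``amplitude_threshold_uv`` is set)
    contain an EEG sample above the threshold are excluded *before* the
    count is truncated to the first ``max_epochs``.
    """
    from .preprocess import reject_epochs  # local import to avoid a cycle

    fs = record.sample_rate_hz
    a, b = span_s
    n_pre = int(round((-a + margin_s) * fs))
    n_tot = int(round((b - a + 2 * margin_s) * fs))
    fe = events.foot(reference_foot)
    hs_times = fe.heel_strikes[fe.heel_valid]
    starts, kept_times = [], []
    for t in hs_times:
        i0 = int(round(t * fs)) - n_pre
        if i0 < 0 or i0 + n_tot > record.n_samples:
            continue
        if invalid_intervals and any(
            t + a + margin_s < hi and t + b + margin_s > lo for lo, hi in invalid_intervals
        ):
            continue
        starts.append(i0)
        kept_times.append(t)
    if not starts:
        raise ValueError("no complete epochs inside the record")
    idx = np.asarray(starts)[:, None] + np.arange(n_tot)[None, :]
    epochs = EpochSet(
        record.data[:, idx].transpose(1, 0, 2),
        fs,
        [c.copy() for c in record.channels],
        t0_index=n_pre,
        span_s=span_s,
        margin_s=margin_s,
        heel_strike_times=np.asarray(kept_times),
        reference_foot=reference_foot,
        history=list(record.history) + [
            f"epoch_signals(foot={reference_foot}, span={span_s}, margin={margin_s})"
        ],
    )
    if amplitude_threshold_uv is not None:
        epochs, _ = reject_epochs(epochs, amplitude_threshold_uv)
    if max_epochs is not None:
        epochs = epochs.truncate(max_epochs)
    return epochs


# ---------------------------------------------------------------------------
# STFT
# ---------------------------------------------------------------------------


def stft(
    epochs: EpochSet,
    channel: str,
    max_freq_hz: float = 100.0,
    window_s: float = STFT_WINDOW_S,
    hop_s: float = STFT_HOP_S,
) -> Spectrogram:
    """Short-time Fourier transform of one channel of an epoch set.

    Hann windows of ``window_s`` are placed at ``hop_s`` increments, fully
    contained in the available samples (no zero padding), and a bin is kept
    when its window centre falls inside the nominal epoch span.  The time
    stamp of each bin is the window centre; the frequency grid is
    ``k / window_s``.
    """
    x = epochs.channel_data(channel)
    fs = epochs.sample_rate_hz
    nw = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    n = x.shape[1]
    if nw > n:
        raise ValueError("STFT window longer than the epoch")
    starts = np.arange(0, n - nw + 1, hop)
    centres = (starts + nw / 2.0 - epochs.t0_index) / fs
    a, b = epochs.span_s
    keep = (centres >= a - _TOL) & (centres < b - _TOL / 2)
    starts, centres = starts[keep], centres[keep]
    win = signal.windows.hann(nw, sym=False)
    # (L, n_windows, nw) windowed segments -> rFFT over the last axis
    seg = x[:, starts[:, None] + np.arange(nw)[None, :]] * win[None, None, :]
    coef = np.fft.rfft(seg, axis=-1)
    freqs = np.fft.rfftfreq(nw, 1.0 / fs)
    fkeep = freqs <= max_freq_hz + _TOL
    return Spectrogram(
        coef[:, :, fkeep].transpose(0, 2, 1),
        freqs[fkeep],
        centres,
        window=f"hann {window_s * 1e3:.0f} ms, hop {hop_s * 1e3:.0f} ms",
        sample_rate_hz=fs,
        channel=channel,
    )


# ---------------------------------------------------------------------------
# spectral measures
# ---------------------------------------------------------------------------


def event_related_power(spec: Spectrogram, mode: str = "percent") -> TimeFreqMap:
    """Event-related power map.

    ``percent`` (EEG): per trial and frequency the power is expressed as
    percent change from its mean over the time bins, then averaged over
    trials -- tonic differences are subtracted away and only phasic,
    gait-locked modulation remains.  ``log`` (EMG): natural log of the
    trial-mean power.
    """
    P = spec.power()
    if mode == "percent":
        m = P.mean(axis=2, keepdims=True)
        if np.any(m == 0):
            raise ValueError("zero mean power at some frequency; degenerate input")
        values = (100.0 * (P - m) / m).mean(axis=0)
        measure = "eeg_power_pct"
    elif mode == "log":
        m = P.mean(axis=0)
        if np.any(m == 0):
            raise ValueError("zero trial-mean power; degenerate input")
        values = np.log(m)
        measure = "emg_power_log"
    else:
        raise ValueError(f"mode must be 'percent' or 'log', got {mode!r}")
    return TimeFreqMap(values, spec.freqs.copy(), spec.times.copy(), measure, spec.n_trials)


def intertrial_coherence(spec: Spectrogram, phase_only: bool = False) -> TimeFreqMap:
    """Inter-trial coherence: consistency of trials locked to heel strike.

    The amplitude-weighted estimator ``|sum_k X_k|^2 / (L sum_k |X_k|^2)``
    is used by default (1 for identical trials, ~1/L under independence);
    ``phase_only=True`` discards single-trial amplitudes first.
    """
    if spec.n_trials < 2:
        raise ValueError("inter-trial coherence needs >= 2 trials")
    X = spec.coef
    if phase_only:
        mag = np.abs(X)
        X = np.where(mag > 0, X / np.where(mag > 0, mag, 1.0), 0.0)
    den = spec.n_trials * (np.abs(X) ** 2).sum(axis=0)
    num = np.abs(X.sum(axis=0)) ** 2
    zero = den == 0
    values = np.divide(num, den, out=np.zeros_like(den), where=~zero)
    out = TimeFreqMap(values, spec.freqs.copy(), spec.times.copy(), "itc_raw", spec.n_trials)
    if zero.any():
        out.mask = ~zero
    return out


def corticomuscular_coherence(spec_eeg: Spectrogram, spec_emg: Spectrogram) -> TimeFreqMap:
    """Magnitude-squared coherence across trials, per time-frequency bin.

    Pairing convention: each EMG channel is paired with the contralateral
    sensorimotor derivation (left TA <-> C4-F4, right TA <-> C3-F3), which
    the caller encodes by its choice of spectrograms.
    """
    spec_eeg._check_grid(spec_emg)
    X, Y = spec_eeg.coef, spec_emg.coef
    num = np.abs((X * np.conj(Y)).sum(axis=0)) ** 2
    den = (np.abs(X) ** 2).sum(axis=0) * (np.abs(Y) ** 2).sum(axis=0)
    zero = den == 0
    values = np.divide(num, den, out=np.zeros_like(den), where=~zero)
    return TimeFreqMap(values, spec_eeg.freqs.copy(), spec_eeg.times.copy(),
                       "coherence_raw", spec_eeg.n_trials)


def coherence_to_z(cmap: TimeFreqMap, n_trials: int | None = None) -> TimeFreqMap:
    """Convert magnitude-squared coherence to standard-normal z-scores.

    Under the null of independent signals the coherence over L segments
    satisfies ``P(C > c) = (1 - c)^(L-1)``; the p-value is mapped through
    the inverse standard normal (one-sided, large coherence -> large
    positive z), in log space for numerical safety, and capped at |z| =
    8.2 where the double-precision quantile saturates.
    """
    L = cmap.n_trials if n_trials is None else n_trials
    if L < 2:
        raise ValueError("z-transform needs L >= 2 trials")
    C = np.clip(cmap.values, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        logp = (L - 1) * np.log1p(-C)  # log of p = (1 - C)^(L-1)
    p = np.exp(logp)
    with np.errstate(divide="ignore"):
        z = norm.isf(p)
    z = np.clip(z, -Z_CAP, Z_CAP)
    measure = cmap.measure.replace("_raw", "") + "_z"
    out = TimeFreqMap(z, cmap.freqs.copy(), cmap.times.copy(), measure, L)
    out.mask = None if cmap.mask is None else cmap.mask.copy()
    return out


def coherence_threshold(n_trials: int, alpha: float = 0.05) -> float:
    """Parametric null threshold ``1 - alpha^(1/(L-1))`` (decreasing in L)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_trials < 2:
        raise ValueError("threshold needs L >= 2 trials")
    return 1.0 - alpha ** (1.0 / (n_trials - 1))


def threshold_map(cmap: TimeFreqMap, n_trials: int | None = None,
                  alpha: float = 0.05) -> TimeFreqMap:
    """Zero out coherence below the (1 - alpha) confidence threshold."""
    L = cmap.n_trials if n_trials is None else n_trials
    thr = coherence_threshold(L, alpha)
    mask = cmap.values >= thr
    values = np.where(mask, cmap.values, 0.0)
    out = TimeFreqMap(values, cmap.freqs.copy(), cmap.times.copy(), cmap.measure, L, mask)
    return out


def band_window_average(
    cmap: TimeFreqMap,
    band,
    window: tuple = DOUBLE_SUPPORT_WINDOW,
) -> BandSummary:
    """Mean of a map over one frequency band and one time window.

    Bin membership is decided by bin centres falling inside the closed
    intervals.  Raises when the selection is empty, listing the grid.
    """
    fi = cmap.band_freq_indices(band)
    ti = cmap.window_time_indices(window)
    if fi.size == 0 or ti.size == 0:
        raise ValueError(
            f"empty band/window selection (band={band}, window={window}); "
            f"freq grid {np.round(cmap.freqs, 3).tolist()}, "
            f"time grid {np.round(cmap.times, 4).tolist()}"
        )
    value = float(cmap.values[np.ix_(fi, ti)].mean())
    band_name = band if isinstance(band, str) else f"{band[0]}-{band[1]}Hz"
    return BandSummary(cmap.measure, band_name, tuple(window), value, cmap.n_trials)


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------


def simulate_null_coherence(
    n_pairs: int = 100,
    n_trials: int = MAX_EPOCHS,
    seed: int = 0,
    sample_rate_hz: float = 2000.0,
    fmin_hz: float = 4.0,
    fmax_hz: float = 100.0,
    alpha: float = 0.05,
):
    """Monte-Carlo null calibration of the coherence estimator.

    Generates ``n_pairs`` independent sets of 1/f-noise "EEG" epochs and
    band-limited-noise "EMG" epochs (L = ``n_trials`` each, 1-s epochs),
    runs the STFT coherence estimator and the z-transform, and pools all
    time-frequency bins with ``fmin_hz <= f <= fmax_hz``.  Overlapping STFT
    windows correlate bins within one trial set, so the Monte-Carlo error
    of the pooled mean is governed by the number of independent pairs, not
    the raw bin count; the default of 100 pairs keeps it below ~0.015 z.

    Returns ``(z, c, threshold)``: the pooled z-scores, the pooled raw
    coherence values and the parametric masking threshold at ``alpha``.
    """
    from .noise import bandlimited_noise, pink_noise

    rng = np.random.default_rng(seed)
    a, b = EPOCH_SPAN
    n = int(round((b - a) * sample_rate_hz))
    zs, cs = [], []
    dummy = [Channel("x", "other", ""), Channel("y", "other", "")]
    for _ in range(n_pairs):
        eeg = np.stack([pink_noise(n, sample_rate_hz, 1.0, rng) for _ in range(n_trials)])
        emg = np.stack(
            [bandlimited_noise(n, sample_rate_hz, 20.0, 450.0, rng) for _ in range(n_trials)]
        )
        epochs = EpochSet(
            np.stack([eeg, emg], axis=1), sample_rate_hz, [c.copy() for c in dummy],
            t0_index=int(round(-a * sample_rate_hz)),
        )
        sx = stft(epochs, "x", max_freq_hz=fmax_hz)
        sy = stft(epochs, "y", max_freq_hz=fmax_hz)
        cmap = corticomuscular_coherence(sx, sy)
        zmap = coherence_to_z(cmap)
        fsel = (cmap.freqs >= fmin_hz - _TOL) & (cmap.freqs <= fmax_hz + _TOL)
        cs.append(cmap.values[fsel].ravel())
        zs.append(zmap.values[fsel].ravel())
    return np.concatenate(zs), np.concatenate(cs), coherence_threshold(n_trials, alpha)
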