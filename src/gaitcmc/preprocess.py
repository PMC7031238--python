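"""Signal conditioning for ambulatory EEG and EMG.

The conditioning chain mirrors standard practice for gait-locked spectral
analysis: unit-variance normalization, zero-phase Butterworth filtering
(EEG band-pass 0.5-70 Hz, EMG high-pass 20 Hz), common average reference,
bipolar sensorimotor derivations (C3-F3, C4-F4), full-wave rectification of
EMG via the Hilbert envelope, amplitude demodulation (unit Hilbert
amplitude, phase preserved) for coherence analysis, and amplitude-based
epoch rejection.

All filters are applied forward-backward (zero phase) so event-locked
latencies are not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len
from scipy.signal import hilbert

from .records import Channel, SignalRecord

#: Default sensorimotor bipolar derivations (anode, cathode, output label).
SENSORIMOTOR_PAIRS = (("C3", "F3", "C3-F3"), ("C4", "F4", "C4-F4"))

#: Relative floor for the instantaneous amplitude in demodulation.
DEMOD_EPS_REL = 1e-8


@dataclass(frozen=True)
class BipolarPair:
    """A differential EEG derivation ``anode - cathode``."""

    anode: str
    cathode: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", f"{self.anode}-{self.cathode}")


def _analytic(x: np.ndarray) -> np.ndarray:
    """Analytic signal with FFT length padded for speed on long records."""
    n = x.shape[-1]
    return hilbert(x, N=next_fast_len(n))[..., :n]


def demodulate(x: np.ndarray, eps_rel: float = DEMOD_EPS_REL):
    """Normalize the instantaneous amplitude of ``x`` to one, keep the phase.

    Subtracts the mean (the analytic phase of a strictly positive signal is
    degenerate), divides by the instantaneous Hilbert amplitude floored at
    ``eps_rel`` times its median, and returns ``(demodulated, n_floored)``.
    The result equals the cosine of the instantaneous phase away from
    floored samples.
    """
    centred = x - x.mean()
    amp = np.abs(_analytic(centred))
    eps = eps_rel * float(np.median(amp))
    n_low = int((amp < eps).sum())
    return centred / np.maximum(amp, eps), n_low


# ---------------------------------------------------------------------------
# record-level operations (each returns a new record, history appended)
# ---------------------------------------------------------------------------


def normalize_variance(record: SignalRecord, roles=("eeg", "emg")) -> SignalRecord:
    """Divide each channel of the selected roles by its standard deviation.

    The divisor is stored in ``channel.extra['norm_sd']`` so later
    amplitude-based rejection can convert thresholds in physical units.
    """
    out = record.copy()
    for i in out.pick(*roles):
        sd = float(out.data[i].std())
        if sd == 0.0:
            raise ValueError(f"channel {out.channels[i].label!r} has zero variance")
        out.data[i] /= sd
        out.channels[i].extra["norm_sd"] = sd * out.channels[i].extra.get("norm_sd", 1.0)
        out.channels[i].units = "unit-variance"
    out.log(f"normalize_variance(roles={tuple(roles)})")
    return out


def filter_eeg(record: SignalRecord, lo_hz: float = 0.5, hi_hz: float = 70.0,
               order: int = 2) -> SignalRecord:
    """Zero-phase Butterworth band-pass of all EEG channels (default 0.5-70 Hz)."""
    if record.sample_rate_hz < 2 * hi_hz:
        raise ValueError(
            f"sample rate {record.sample_rate_hz} Hz below Nyquist for {hi_hz} Hz upper edge"
        )
    idx = record.pick("eeg", "eeg-bipolar")
    if not idx:
        raise ValueError("record has no EEG channels")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass",
                        fs=record.sample_rate_hz, output="sos")
    out = record.copy()
    out.data[idx] = signal.sosfiltfilt(sos, out.data[idx], axis=-1)
    out.log(f"filter_eeg(butterworth order={order}, band=[{lo_hz}, {hi_hz}] Hz, zero-phase)")
    return out


def rereference_car(record: SignalRecord) -> SignalRecord:
    """Common average reference: subtract the mean over monopolar EEG channels."""
    idx = record.pick("eeg")
    if len(idx) < 2:
        raise ValueError("common average reference needs >= 2 EEG channels")
    out = record.copy()
    out.data[idx] -= out.data[idx].mean(axis=0, keepdims=True)
    out.log(f"rereference_car(n_channels={len(idx)})")
    return out


def bipolar_derive(record: SignalRecord, pairs=None) -> SignalRecord:
    """Append differential channels ``anode - cathode`` with role eeg-bipolar."""
    if pairs is None:
        pairs = [BipolarPair(*p) for p in SENSORIMOTOR_PAIRS]
    out = record.copy()
    for pair in pairs:
        a, c = out.get(pair.anode), out.get(pair.cathode)
        sd_a = out.channel(pair.anode).extra.get("norm_sd", 1.0)
        sd_c = out.channel(pair.cathode).extra.get("norm_sd", 1.0)
        extra = {"anode": pair.anode, "cathode": pair.cathode,
                 # upper bound on the physical scale of the difference signal,
                 # used when converting amplitude thresholds in uV
                 "norm_sd": float(np.hypot(sd_a, sd_c))}
        out.append_channel(a - c, Channel(pair.label, "eeg-bipolar",
                                          out.channel(pair.anode).units, extra))
    out.log(f"bipolar_derive(pairs={[p.label for p in pairs]})")
    return out


def preprocess_emg(record: SignalRecord, hp_hz: float = 20.0, order: int = 4) -> SignalRecord:
    """Rectify and demodulate every EMG channel.

    For each channel with role ``emg`` two derived channels are appended:

    * ``<label>_rect`` -- full-wave rectified EMG, the modulus of the
      analytic signal of the zero-phase 20-Hz-high-passed EMG.  Used for
      envelope analysis and EMG power.
    * ``<label>_demod`` -- demodulated EMG: the mean-subtracted rectified
      signal divided by its instantaneous (Hilbert) amplitude, i.e. unit
      amplitude with the instantaneous phase preserved.  Used for coherence
      analysis, where periodic amplitude modulation would otherwise produce
      spurious coherence.  The amplitude is floored at
      ``1e-8 x median amplitude`` to avoid division blow-up on silent EMG.
    """
    idx = record.pick("emg")
    if not idx:
        raise ValueError("record has no EMG channels")
    sos = signal.butter(order, hp_hz, btype="highpass", fs=record.sample_rate_hz, output="sos")
    out = record.copy()
    for i in idx:
        ch = out.channels[i]
        hp = signal.sosfiltfilt(sos, out.data[i])
        rect = np.abs(_analytic(hp))
        out.append_channel(rect, Channel(f"{ch.label}_rect", "emg-rectified", ch.units,
                                         dict(ch.extra, source=ch.label)))
        demod, n_low = demodulate(rect)
        out.append_channel(demod, Channel(f"{ch.label}_demod", "emg-demodulated", "",
                                          dict(ch.extra, source=ch.label)))
        if n_low > 0.01 * demod.size:
            out.log(f"warning: {ch.label} instantaneous amplitude below floor on "
                    f"{n_low / demod.size:.1%} of samples")
    out.log(f"preprocess_emg(hp={hp_hz} Hz order={order} zero-phase, hilbert rectification, "
            "amplitude demodulation)")
    return out


# ---------------------------------------------------------------------------
# epoch-level rejection
# ---------------------------------------------------------------------------


@dataclass
class RejectionReport:
    threshold_uv: float
    rejected_indices: np.ndarray
    n_total: int

    @property
    def fraction_rejected(self) -> float:
        return len(self.rejected_indices) / self.n_total if self.n_total else 0.0


def reject_epochs(epochs, amplitude_threshold_uv: float = 300.0, roles=("eeg",)):
    """Drop epochs in which any EEG sample exceeds the amplitude threshold.

    The threshold is specified in microvolts; channels that were normalized
    to unit variance are converted back through the ``norm_sd`` recorded in
    their metadata.  Returns the reduced epoch set and a report of the
    rejected indices.  Raises when every epoch is rejected, which indicates
    the threshold needs review.
    """
    from .spectral import EpochSet  # local import to avoid a cycle

    assert isinstance(epochs, EpochSet)
    keep = np.ones(epochs.n_epochs, dtype=bool)
    for ci, ch in enumerate(epochs.channels):
        if ch.role not in roles:
            continue
        thr = amplitude_threshold_uv / ch.extra.get("norm_sd", 1.0)
        keep &= np.abs(epochs.data[:, ci, :]).max(axis=-1) <= thr
    rejected = np.flatnonzero(~keep)
    if not keep.any():
        raise ValueError(
            f"all {epochs.n_epochs} epochs exceed {amplitude_threshold_uv} uV; "
            "review the rejection threshold"
        )
    out = epochs.select(keep)
    out.history.append(
        f"reject_epochs(threshold={amplitude_threshold_uv} uV): removed {rejected.size} of "
        f"{epochs.n_epochs}"
    )
    return out, RejectionReport(amplitude_threshold_uv, rejected, epochs.n_epochs)
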