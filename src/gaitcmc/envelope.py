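"""Event-related EMG envelopes and foot-lift / foot-drop amplitude summaries.

The tibialis anterior envelope over the gait cycle shows two bursts: one
during early swing (foot lift) and a double-peaked one around heel strike
(foot drop, peaks at t = 0 and ~60 ms).  Per-trial rectified EMG is
smoothed with a zero-phase 2nd-order 45-Hz low-pass, averaged over trials
and expressed as a percentage of the peak amplitude within the gait cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy import stats as sstats

from .spectral import EpochSet

#: Named analysis windows, seconds relative to heel strike.
ENVELOPE_WINDOWS = {
    "foot_lift": (-0.40, -0.25),
    "foot_drop": (0.04, 0.08),
}

_TOL = 1e-9


@dataclass
class EnvelopeProfile:
    """Trial-averaged EMG envelope as % of the within-cycle peak."""

    times: np.ndarray
    amplitude_pct: np.ndarray
    muscle: str
    n_trials: int

    def window_indices(self, window) -> np.ndarray:
        a, b = ENVELOPE_WINDOWS[window] if isinstance(window, str) else window
        return np.flatnonzero((self.times >= a - _TOL) & (self.times <= b + _TOL))


def emg_envelope(
    epochs: EpochSet,
    channel: str,
    smooth_hz: float = 45.0,
    order: int = 2,
    peak_scope: str = "full",
) -> EnvelopeProfile:
    """Event-related envelope of one rectified EMG channel.

    Each trial's rectified signal is low-pass filtered (zero phase,
    ``smooth_hz`` cut-off), the trials are averaged, and the profile is
    normalized so the peak within the gait cycle equals 100%.  With
    ``peak_scope='full'`` the peak is searched over all available samples
    of the epoch (including any margin, approximating the full stride);
    ``'window'`` restricts it to the nominal epoch span.  The profile
    itself is reported on the nominal span.
    """
    x = epochs.channel_data(channel)
    sos = signal.butter(order, smooth_hz, btype="lowpass",
                        fs=epochs.sample_rate_hz, output="sos")
    smoothed = signal.sosfiltfilt(sos, x, axis=-1)
    mean_env = smoothed.mean(axis=0)
    times = epochs.times
    a, b = epochs.span_s
    nominal = (times >= a - _TOL) & (times < b - _TOL)
    if peak_scope == "full":
        peak = float(mean_env.max())
    elif peak_scope == "window":
        peak = float(mean_env[nominal].max())
    else:
        raise ValueError("peak_scope must be 'full' or 'window'")
    if peak <= 0:
        raise ValueError("envelope peak is zero; cannot normalize")
    return EnvelopeProfile(
        times[nominal].copy(),
        100.0 * mean_env[nominal] / peak,
        muscle=channel,
        n_trials=epochs.n_epochs,
    )


def window_amplitude(profile: EnvelopeProfile, window) -> float:
    """Mean envelope amplitude (%) over a closed time window.

    ``window`` is a name from :data:`ENVELOPE_WINDOWS` (``foot_lift``:
    -0.4..-0.25 s, ``foot_drop``: 0.04..0.08 s) or an explicit
    ``(start, stop)`` pair.
    """
    idx = profile.window_indices(window)
    if idx.size == 0:
        raise ValueError(
            f"window {window!r} outside the envelope grid "
            f"[{profile.times[0]:.3f}, {profile.times[-1]:.3f}] s"
        )
    return float(profile.amplitude_pct[idx].mean())


def correlate_envelope_cmc(amplitudes, cmc_values, method: str = "pearson"):
    """Correlate per-record EMG amplitudes with per-record coherence.

    Returns ``(r, p)`` from a two-sided Pearson test (or Spearman with
    ``method='spearman'``).  Requires >= 3 paired records and non-zero
    variance in both variables.
    """
    x = np.asarray(amplitudes, dtype=float)
    y = np.asarray(cmc_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("amplitudes and cmc_values must be 1-D and the same length")
    if x.size < 3:
        raise ValueError("need >= 3 paired records")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        res = sstats.pearsonr(x, y)
    elif method == "spearman":
        res = sstats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)
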