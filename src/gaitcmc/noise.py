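"""Stochastic signal primitives shared by the generator and calibration code."""

from __future__ import annotations

import numpy as np
from scipy import signal


def pink_noise(n: int, fs: float, exponent: float, rng: np.random.Generator,
               floor_hz: float = 0.5) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping of white noise.

    The shaping is floored below ``floor_hz`` to keep sub-delta drift
    bounded (the analysis high-passes at 0.5 Hz anyway).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.maximum(f, floor_hz) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x / x.std()


def bandlimited_noise(n: int, fs: float, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()
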