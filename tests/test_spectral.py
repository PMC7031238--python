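"""Epoching, STFT grid, coherence estimators and their parametric null."""

import numpy as np
import pytest
from scipy.special import erfinv

from gaitcmc import (
    Channel,
    SignalRecord,
    SynthConfig,
    band_window_average,
    coherence_threshold,
    coherence_to_z,
    corticomuscular_coherence,
    epoch_signals,
    event_related_power,
    generate_record,
    intertrial_coherence,
    stft,
    threshold_map,
)
from gaitcmc.events import EventSeries, FootEvents
from gaitcmc.spectral import EpochSet, Spectrogram, TimeFreqMap

FS = 2000.0
DF = 1.0 / 0.375  # STFT frequency resolution


def _spec(coef):
    coef = np.asarray(coef, dtype=complex)
    L, F, T = coef.shape
    return Spectrogram(coef, np.arange(F) * DF, np.arange(T) * 0.025, "test", FS)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------


def coherence_oracle(X, Y):
    """Loop-based evaluation of the defining sums, one bin at a time."""
    L, F, T = X.shape
    out = np.zeros((F, T))
    for f in range(F):
        for t in range(T):
            num = 0.0 + 0.0j
            px = py = 0.0
            for k in range(L):
                num += X[k, f, t] * np.conj(Y[k, f, t])
                px += abs(X[k, f, t]) ** 2
                py += abs(Y[k, f, t]) ** 2
            out[f, t] = abs(num) ** 2 / (px * py)
    return out


def itc_oracle(X):
    L, F, T = X.shape
    out = np.zeros((F, T))
    for f in range(F):
        for t in range(T):
            s = sum(X[k, f, t] for k in range(L))
            p = sum(abs(X[k, f, t]) ** 2 for k in range(L))
            out[f, t] = abs(s) ** 2 / (L * p)
    return out


def percent_power_oracle(X):
    L, F, T = X.shape
    out = np.zeros((F, T))
    for k in range(L):
        for f in range(F):
            p = np.array([abs(X[k, f, t]) ** 2 for t in range(T)])
            out[f] += 100.0 * (p - p.mean()) / p.mean()
    return out / L


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


def _zeros_record(duration_s=10.0, n_ch=1):
    chans = [Channel(f"ch{i}", "eeg") for i in range(n_ch)]
    return SignalRecord(np.zeros((n_ch, int(duration_s * FS))), FS, chans)


def _single_foot_events(times):
    fe = FootEvents(np.asarray(times, float), np.empty(0))
    return EventSeries(fe, FootEvents(np.empty(0), np.empty(0)))


class TestEpoching:
    def test_window_boundary_drops_incomplete_epoch(self):
        ev = _single_foot_events([0.5, 5.0])
        epochs = epoch_signals(_zeros_record(), ev, margin_s=0.0)
        assert epochs.n_epochs == 1
        assert epochs.heel_strike_times[0] == 5.0

    def test_epoch_length_and_alignment(self):
        ev = _single_foot_events([5.0])
        epochs = epoch_signals(_zeros_record(), ev, margin_s=0.0)
        assert epochs.data.shape[-1] == 2000  # exactly 1 s
        assert epochs.t0_index == 1600
        assert epochs.times[0] == pytest.approx(-0.8)

    def test_fewer_than_max_keeps_all(self):
        ev = _single_foot_events(np.arange(2.0, 8.0, 1.1))
        epochs = epoch_signals(_zeros_record(), ev, max_epochs=220)
        assert epochs.n_epochs == len(ev.left.heel_strikes)

    def test_truncation_to_max(self):
        ev = _single_foot_events(np.arange(2.0, 58.0, 1.1))
        epochs = epoch_signals(_zeros_record(60.0), ev, max_epochs=10)
        assert epochs.n_epochs == 10

    def test_invalid_interval_overlap_excluded(self):
        ev = _single_foot_events([3.0, 6.0])
        epochs = epoch_signals(_zeros_record(), ev, invalid_intervals=[(5.5, 5.9)])
        assert epochs.n_epochs == 1

    def test_no_epochs_raises(self):
        ev = _single_foot_events([0.1])
        with pytest.raises(ValueError, match="no complete epochs"):
            epoch_signals(_zeros_record(2.0), ev)


class TestSTFT:
    def _epochs_from(self, x_trials):
        x = np.asarray(x_trials)
        return EpochSet(x[:, None, :], FS, [Channel("x", "eeg")], t0_index=1600)

    def test_26_window_positions_on_bare_epoch(self):
        epochs = self._epochs_from(np.zeros((2, 2000)))
        spec = stft(epochs, "x")
        assert spec.times.size == 26  # floor((2000-750)/50)+1 fully-contained placements
        assert spec.times[0] == pytest.approx(-0.6125)
        assert spec.times[-1] == pytest.approx(0.0125)

    def test_margin_grid_tiles_the_nominal_span(self):
        x = np.zeros((2, 1, 2750))
        epochs = EpochSet(x, FS, [Channel("x", "eeg")], t0_index=1975, margin_s=0.1875)
        spec = stft(epochs, "x")
        assert spec.times.size == 40
        assert spec.times[0] == pytest.approx(-0.8)
        assert spec.times[-1] == pytest.approx(0.175)
        assert np.any(np.isclose(spec.times, 0.0)) and np.any(np.isclose(spec.times, 0.125))

    def test_sinusoid_hits_grid_bin_with_analytic_power(self, rng):
        """A 16 Hz unit sinusoid lands on bin k=6; |X| ~ sum(w)/2 = N/4."""
        t = np.arange(2000) / FS
        phases = rng.uniform(0, 2 * np.pi, size=3)
        epochs = self._epochs_from([np.sin(2 * np.pi * 16.0 * t + p) for p in phases])
        spec = stft(epochs, "x")
        power = spec.power().mean(axis=(0, 2))
        k = int(np.argmax(power))
        assert spec.freqs[k] == pytest.approx(16.0)
        assert power[k] == pytest.approx((750 / 4) ** 2, rel=0.05)

    def test_zero_signal_zero_coefficients(self):
        spec = stft(self._epochs_from(np.zeros((2, 2000))), "x")
        assert np.all(spec.coef == 0)

    def test_missing_channel(self):
        with pytest.raises(KeyError):
            stft(self._epochs_from(np.zeros((2, 2000))), "nope")


class TestEventRelatedPower:
    def test_constant_power_gives_zero_percent_map(self):
        coef = np.full((4, 3, 8), 2.0 + 0.0j)
        out = event_related_power(_spec(coef), "percent")
        assert np.allclose(out.values, 0.0)

    def test_percent_map_zero_mean_over_time(self, rng):
        coef = rng.standard_normal((5, 4, 10)) + 1j * rng.standard_normal((5, 4, 10))
        out = event_related_power(_spec(coef), "percent")
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-10)

    def test_two_to_one_power_split(self):
        coef = np.ones((2, 1, 8), dtype=complex)
        coef[:, :, :4] = np.sqrt(2.0)  # power 2 vs 1
        out = event_related_power(_spec(coef), "percent")
        assert np.allclose(out.values[0, :4], 100 / 3, atol=1e-9)
        assert np.allclose(out.values[0, 4:], -100 / 3, atol=1e-9)

    def test_oracle_equivalence_percent(self, rng):
        coef = rng.standard_normal((5, 3, 4)) + 1j * rng.standard_normal((5, 3, 4))
        out = event_related_power(_spec(coef), "percent")
        assert np.allclose(out.values, percent_power_oracle(coef), atol=1e-12)

    def test_log_mode(self, rng):
        coef = rng.standard_normal((6, 2, 5)) + 1j * rng.standard_normal((6, 2, 5))
        out = event_related_power(_spec(coef), "log")
        assert np.allclose(out.values, np.log((np.abs(coef) ** 2).mean(axis=0)), atol=1e-12)

    def test_zero_power_raises(self):
        with pytest.raises(ValueError, match="zero"):
            event_related_power(_spec(np.zeros((3, 2, 4), dtype=complex)), "percent")


class TestCoherenceEstimators:
    def test_identical_trials_give_itc_one(self, rng):
        one = rng.standard_normal((1, 3, 5)) + 1j * rng.standard_normal((1, 3, 5))
        coef = np.repeat(one, 6, axis=0)
        out = intertrial_coherence(_spec(coef))
        assert np.allclose(out.values, 1.0, atol=1e-12)

    def test_itc_oracle_equivalence(self, rng):
        coef = rng.standard_normal((4, 2, 3)) + 1j * rng.standard_normal((4, 2, 3))
        out = intertrial_coherence(_spec(coef))
        assert np.allclose(out.values, itc_oracle(coef), atol=1e-12)

    def test_itc_null_expectation_is_one_over_L(self, rng):
        L = 4
        coef = rng.standard_normal((L, 40, 50)) + 1j * rng.standard_normal((L, 40, 50))
        out = intertrial_coherence(_spec(coef))
        assert out.values.mean() == pytest.approx(1 / L, rel=0.05)

    def test_cmc_identity(self, rng):
        coef = rng.standard_normal((3, 2, 4)) + 1j * rng.standard_normal((3, 2, 4))
        out = corticomuscular_coherence(_spec(coef), _spec(coef.copy()))
        assert np.allclose(out.values, 1.0, atol=1e-12)

    def test_cmc_oracle_equivalence_toy(self, rng):
        X = rng.standard_normal((3, 2, 4)) + 1j * rng.standard_normal((3, 2, 4))
        Y = rng.standard_normal((3, 2, 4)) + 1j * rng.standard_normal((3, 2, 4))
        out = corticomuscular_coherence(_spec(X), _spec(Y))
        assert np.allclose(out.values, coherence_oracle(X, Y), atol=1e-12)

    def test_cmc_null_expectation_is_one_over_L(self, rng):
        L = 5
        shape = (L, 40, 50)
        X = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        Y = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        out = corticomuscular_coherence(_spec(X), _spec(Y))
        assert out.values.mean() == pytest.approx(1 / L, rel=0.05)

    def test_scaling_invariance(self, rng):
        X = rng.standard_normal((4, 3, 5)) + 1j * rng.standard_normal((4, 3, 5))
        Y = rng.standard_normal((4, 3, 5)) + 1j * rng.standard_normal((4, 3, 5))
        c1 = corticomuscular_coherence(_spec(X), _spec(Y)).values
        c2 = corticomuscular_coherence(_spec(17.0 * X), _spec(0.01 * Y)).values
        assert np.allclose(c1, c2, atol=1e-12)
        assert np.all((c1 >= 0) & (c1 <= 1 + 1e-12))

    def test_grid_mismatch_raises(self, rng):
        X = rng.standard_normal((3, 2, 4)) + 1j * np.zeros((3, 2, 4))
        with pytest.raises(ValueError, match="grids"):
            corticomuscular_coherence(_spec(X), _spec(X[:, :, :3]))


class TestZTransform:
    def test_closed_form_example(self):
        """C = 0.5, L = 11: p = 0.5^10; z from an independent quantile route."""
        cmap = TimeFreqMap(np.array([[0.5]]), np.array([16.0]), np.array([0.0]), "coh", 11)
        z = coherence_to_z(cmap).values[0, 0]
        p = 0.5 ** 10
        assert p == pytest.approx(9.765625e-4)
        z_expected = np.sqrt(2) * erfinv(1 - 2 * p)
        assert z == pytest.approx(z_expected, abs=1e-9)

    def test_zero_coherence_floors(self):
        cmap = TimeFreqMap(np.array([[0.0]]), np.array([16.0]), np.array([0.0]), "coh", 50)
        assert coherence_to_z(cmap).values[0, 0] == -8.2

    def test_full_coherence_caps(self):
        cmap = TimeFreqMap(np.array([[1.0]]), np.array([16.0]), np.array([0.0]), "coh", 50)
        assert coherence_to_z(cmap).values[0, 0] == 8.2

    def test_needs_two_trials(self):
        cmap = TimeFreqMap(np.array([[0.5]]), np.array([16.0]), np.array([0.0]), "coh", 1)
        with pytest.raises(ValueError, match="L >= 2"):
            coherence_to_z(cmap)

    def test_null_itc_z_is_standard_normal(self, rng):
        """z-scored ITC of independent circular-Gaussian trials ~ N(0, 1)."""
        L = 220
        coef = rng.standard_normal((L, 60, 180)) + 1j * rng.standard_normal((L, 60, 180))
        z = coherence_to_z(intertrial_coherence(_spec(coef))).values.ravel()
        assert z.size > 1e4
        assert abs(z.mean()) < 0.05
        assert abs(z.std() - 1.0) < 0.05


class TestThreshold:
    def test_closed_form_value(self):
        thr = coherence_threshold(220, 0.05)
        assert thr == pytest.approx(1.0 - np.exp(np.log(0.05) / 219), abs=1e-12)
        assert thr == pytest.approx(0.01359, abs=5e-5)

    def test_threshold_decreases_with_trials(self):
        ls = [10, 50, 100, 220]
        ths = [coherence_threshold(L) for L in ls]
        assert all(a > b for a, b in zip(ths, ths[1:]))

    def test_alpha_limit_and_validation(self):
        assert coherence_threshold(100, 1 - 1e-12) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError, match="alpha"):
            coherence_threshold(100, 1.5)

    def test_masked_values_are_zero_exactly(self, rng):
        vals = rng.uniform(0, 0.05, size=(5, 6))
        cmap = TimeFreqMap(vals, np.arange(5.0), np.arange(6.0) * 0.025, "coh", 220)
        out = threshold_map(cmap)
        thr = coherence_threshold(220)
        assert np.all(out.values[vals < thr] == 0.0)
        assert np.all(out.values[vals >= thr] == vals[vals >= thr])
        assert np.array_equal(out.mask, vals >= thr)


class TestBandWindowAverage:
    def _map(self, values, freqs, times):
        return TimeFreqMap(values, np.asarray(freqs, float), np.asarray(times, float), "m", 100)

    def test_constant_map(self):
        cmap = self._map(np.full((40, 40), 3.25), np.arange(40) * DF, np.arange(40) * 0.025 - 0.8)
        assert band_window_average(cmap, "low_beta").value == pytest.approx(3.25)

    def test_low_beta_bin_selection_on_stft_grid(self):
        freqs = np.arange(40) * DF
        cmap = self._map(np.zeros((40, 5)), freqs, np.arange(5) * 0.025)
        sel = freqs[cmap.band_freq_indices("low_beta")]
        assert np.allclose(sel, [5 * DF, 6 * DF, 7 * DF])  # 13.33, 16.0, 18.67 Hz
        assert band_window_average(cmap, "low_beta").n_trials == 100

    def test_closed_window_selects_boundary_bins(self):
        times = np.arange(-4, 9) * 0.025  # -0.1 .. 0.2 s
        cmap = self._map(np.zeros((3, times.size)), [13.33, 16.0, 18.67], times)
        sel = times[cmap.window_time_indices((0.0, 0.125))]
        assert np.allclose(sel, [0.0, 0.025, 0.05, 0.075, 0.1, 0.125])

    def test_empty_selection_raises_with_grid(self):
        cmap = self._map(np.zeros((2, 2)), [100.0, 200.0], [0.0, 0.025])
        with pytest.raises(ValueError, match="grid"):
            band_window_average(cmap, "theta")


class TestPipelineEpochCounts:
    def test_record_epoching_matches_truth(self):
        cfg = SynthConfig(duration_s=40, seed=21)
        record, truth = generate_record(cfg)
        epochs = epoch_signals(record, truth.event_series, margin_s=0.1875, max_epochs=None)
        hs = truth.event_series.left.heel_strikes
        a, b = -0.8 - 0.1875, 0.2 + 0.1875
        expected = int(np.sum((hs + a >= 0) & (hs + b <= cfg.duration_s)))
        assert epochs.n_epochs == expected
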