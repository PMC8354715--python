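"""Spectra, spectral exponent, Morlet decomposition and bootstrap masks."""

import numpy as np
import pytest

from percort import timefreq as tfr
from percort.timefreq import (
    Spectrum,
    band_average,
    bootstrap_mask_power,
    morlet_tf,
    periodogram_mean,
    power_db,
    spectral_exponent,
)

from conftest import make_epochs


class TestPeriodogram:
    def test_sinusoid_peak_power(self):
        rate, amp, f0 = 500.0, 8.0, 10.0
        t = -5.0 + np.arange(5000) / rate
        data = amp * np.sin(2 * np.pi * f0 * t)[None, None, :] * np.ones((3, 1, 1))
        spec = periodogram_mean(make_epochs(data), window=(-5.0, -1.0))
        k = np.argmin(np.abs(spec.frequencies - f0))
        assert spec.frequencies[k] == pytest.approx(f0)
        assert spec.power[k] == pytest.approx(amp**2 / 4, rel=1e-9)

    def test_zero_signal_zero_spectrum(self):
        spec = periodogram_mean(make_epochs(np.zeros((2, 1, 5000))), window=(-5.0, -1.0))
        assert np.all(spec.power == 0)

    def test_parseval_two_sided(self, rng):
        data = rng.normal(0, 5, size=(4, 1, 5000))
        ep = make_epochs(data)
        spec = periodogram_mean(ep, window=(-5.0, -1.0))
        seg = ep.data[:, 0, ep.slice((-5.0, -1.0))]
        assert spec.two_sided_sum() == pytest.approx(float((seg**2).mean()), rel=1e-6)


class TestSpectralExponent:
    def test_flat_spectrum_slope_zero(self):
        f = np.linspace(1, 60, 120)
        spec = Spectrum(f, np.ones_like(f), 1, 240)
        assert spectral_exponent(spec) == pytest.approx(0.0, abs=1e-12)

    def test_powerlaw_recovered_exactly(self):
        f = np.linspace(1, 60, 120)
        spec = Spectrum(f, f**-2.0, 1, 240)
        assert spectral_exponent(spec) == pytest.approx(-2.0, abs=1e-9)

    def test_scale_invariance(self):
        f = np.linspace(1, 60, 120)
        p = f**-1.3
        s1 = spectral_exponent(Spectrum(f, p, 1, 240))
        s2 = spectral_exponent(Spectrum(f, 77.7 * p, 1, 240))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_nonpositive_power_rejected(self):
        f = np.linspace(1, 60, 120)
        p = np.ones_like(f)
        p[50] = 0.0
        with pytest.raises(ValueError):
            spectral_exponent(Spectrum(f, p, 1, 240))


class TestMorlet:
    def test_sinusoid_peaks_at_its_frequency(self):
        rate = 500.0
        t = -5.0 + np.arange(5000) / rate
        data = np.sin(2 * np.pi * 10 * t)[None, None, :] * np.ones((2, 1, 1))
        tf = morlet_tf(make_epochs(data))
        mid = tf.slice((-0.01, 0.01)).start
        power = np.abs(tf.coefficients[0, 0, :, mid]) ** 2
        assert tf.frequencies[np.argmax(power)] == 10.0

    def test_magnitude_invariant_to_input_phase(self):
        rate = 500.0
        t = -5.0 + np.arange(5000) / rate
        a = np.sin(2 * np.pi * 10 * t)
        b = np.sin(2 * np.pi * 10 * t + 1.1)
        tf = morlet_tf(make_epochs(np.stack([a, b])[:, None, :]), dtype=np.complex128)
        sl = tf.slice((-1.0, 1.0))
        ma = np.abs(tf.coefficients[0, 0, 9, sl])
        mb = np.abs(tf.coefficients[1, 0, 9, sl])
        # equal up to the ripple from truncating the Gaussian envelope at 4 SD
        assert np.allclose(ma, mb, rtol=1e-3)

    def test_matches_time_domain_convolution(self, rng):
        from scipy.fft import next_fast_len

        from percort.timefreq import _morlet_kernel

        rate = 500.0
        data = rng.normal(size=(2, 1, 2000))
        ep = make_epochs(data, t0=-2.0)
        freqs = np.array([5.0, 11.0, 23.0])
        tf = morlet_tf(ep, freqs=freqs, dtype=np.complex128)
        max_half = int(np.ceil(4 * 3.0 / (2 * np.pi * freqs.min()) * rate))
        nfft = next_fast_len(2000 + 2 * max_half)
        for fi, f in enumerate(freqs):
            w = _morlet_kernel(f, rate, 3.0)
            w = w / np.abs(np.fft.fft(w, nfft)).max()
            for tr in range(2):
                direct = np.convolve(data[tr, 0], w, mode="same")
                got = tf.coefficients[tr, 0, fi]
                assert np.abs(got - direct).max() < 1e-8 * np.abs(direct).max()

    def test_frequency_above_nyquist_rejected(self, short_epochs):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_tf(short_epochs, freqs=np.array([10.0, 300.0]))


def _tf_of(data, t0=-5.0):
    return morlet_tf(make_epochs(data, t0=t0), crop=(-0.7, 0.9))


class TestPowerDB:
    def test_amplitude_doubling_gives_6db(self):
        rate = 500.0
        t = -5.0 + np.arange(5000) / rate
        carrier = np.sin(2 * np.pi * 10 * t)
        amp = np.where((t >= 0) & (t < 0.5), 2.0, 1.0)
        data = (amp * carrier)[None, None, :] * np.ones((3, 1, 1))
        pm = power_db(_tf_of(data))
        sl = pm.slice((0.15, 0.35))
        assert pm.values[0, 9, sl].mean() == pytest.approx(10 * np.log10(4), abs=0.1)

    def test_db_map_scale_invariant(self, rng):
        data = rng.normal(size=(4, 2, 5000))
        a = power_db(_tf_of(data))
        b = power_db(_tf_of(data * 13.7))
        assert np.allclose(a.values, b.values, atol=1e-4)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            power_db(_tf_of(np.zeros((3, 1, 5000))))


class TestBootstrapMask:
    def test_masked_entries_zero_and_rest_raw(self, rng):
        data = rng.normal(size=(20, 2, 5000))
        tf = _tf_of(data)
        pm = bootstrap_mask_power(tf, n_perm=200, alpha=0.05, seed=1)
        assert np.all(pm.values[~pm.mask] == 0.0)
        assert np.array_equal(pm.values[pm.mask], pm.raw[pm.mask])

    def test_type_one_error_controlled(self, rng):
        # stationary signal: response distributed like baseline
        data = rng.normal(size=(90, 2, 5000))
        tf = _tf_of(data)
        pm = bootstrap_mask_power(tf, n_perm=500, alpha=0.05, seed=2)
        resp = pm.mask[:, :, pm.slice((0.0, 0.8))]
        assert resp.mean() <= 0.05 + 0.02

    def test_planted_burst_detected(self, rng):
        rate = 500.0
        t = -5.0 + np.arange(5000) / rate
        data = rng.normal(0, 1, size=(30, 1, 5000))
        burst = 8 * np.sin(2 * np.pi * 10 * t) * ((t >= 0.1) & (t < 0.4))
        data += burst[None, None, :]
        tf = _tf_of(data)
        pm = bootstrap_mask_power(tf, n_perm=500, alpha=0.05, seed=3)
        sl = pm.slice((0.15, 0.35))
        assert pm.mask[0, 9, sl].all()
        assert pm.values[0, 9, sl].min() > 0

    def test_insufficient_permutations_rejected(self, rng):
        tf = _tf_of(rng.normal(size=(5, 1, 5000)))
        with pytest.raises(ValueError):
            bootstrap_mask_power(tf, n_perm=10, alpha=0.05, seed=1)


class TestBandAverage:
    def _pm(self, values):
        n_ch, n_f, n_t = values.shape
        return tfr.PowerMap(
            values=values, frequencies=np.arange(1.0, n_f + 1),
            time_axis=np.arange(n_t) / 500.0, rate=500.0,
            channel_labels=[f"C{i}" for i in range(n_ch)], baseline=(-0.5, -0.2),
        )

    def test_all_masked_zero(self):
        pm = self._pm(np.zeros((2, 40, 100)))
        assert band_average(pm, (8, 14), (0.0, 0.1)) == 0.0

    def test_uniform_minus_one(self):
        pm = self._pm(-np.ones((2, 40, 100)))
        assert band_average(pm, (8, 14), (0.0, 0.1)) == -1.0

    def test_matches_bruteforce_loop(self, rng):
        vals = rng.normal(size=(3, 40, 100))
        pm = self._pm(vals)
        band, window = (8, 14), (0.02, 0.1)
        got = band_average(pm, band, window, channels=[0, 2])
        acc, n = 0.0, 0
        for ch in (0, 2):
            for fi, f in enumerate(pm.frequencies):
                if band[0] <= f <= band[1]:
                    for ti, t in enumerate(pm.time_axis):
                        if window[0] <= t < window[1] - 1e-12:
                            acc += vals[ch, fi, ti]
                            n += 1
        assert got == pytest.approx(acc / n, abs=1e-12)
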