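"""Scalar evoked features: early rms, slow component, OFF period, late HF, LF."""

import numpy as np
import pytest

from percort import synthetic as syn
from percort import timefreq as tfr
from percort.evoked_features import (
    detect_hf_suppression,
    detect_late_hf,
    early_erp_rms,
    lf_features,
    off_period_summary,
    slow_component,
)

from conftest import make_epochs


class TestEarlyERP:
    def test_zero_and_constant(self):
        ep = make_epochs(np.zeros((3, 2, 5000)))
        per, mean = early_erp_rms(ep)
        assert mean == 0.0
        data = np.zeros((3, 2, 5000))
        sl = ep.slice((0.006, 0.05))
        data[:, :, sl] = 10.0
        per, mean = early_erp_rms(make_epochs(data))
        assert mean == pytest.approx(10.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        ep = make_epochs(rng.normal(size=(4, 3, 5000)))
        per, mean = early_erp_rms(ep)
        sl = ep.slice((0.006, 0.05))
        erp = ep.data.mean(axis=0)[:, sl]
        want = np.array([np.sqrt(np.mean([v**2 for v in row])) for row in erp])
        assert np.allclose(per, want, atol=1e-12)
        assert mean == pytest.approx(want.mean(), abs=1e-12)


class TestSlowComponent:
    def test_lowpass_transfer(self):
        rate = 500.0
        t = -5.0 + np.arange(5000) / rate
        slow = np.sin(2 * np.pi * 1 * t)
        fast = np.sin(2 * np.pi * 30 * t)
        sc_slow = slow_component(make_epochs(slow[None, None, :] * np.ones((2, 1, 1))))
        sc_fast = slow_component(make_epochs(fast[None, None, :] * np.ones((2, 1, 1))))
        # a 1 Hz wave passes (<1% loss); a 30 Hz wave is attenuated >95%
        assert sc_slow.spontaneous_rms_uv > 0.99 / np.sqrt(2)
        assert sc_fast.spontaneous_rms_uv < 0.05 / np.sqrt(2)

    def test_planted_halfwave_latency(self):
        rate = 500.0
        t = -5.0 + np.arange(5000) / rate
        dur = 2 * 0.13  # 0.5 Hz-ish half wave peaking at 0.13 s
        wave = np.where((t >= 0) & (t <= dur), np.sin(np.pi * np.clip(t, 0, dur) / dur), 0.0)
        sc = slow_component(make_epochs(30 * wave[None, None, :] * np.ones((3, 1, 1))))
        assert sc.sc_max_latency_s[0] == pytest.approx(0.13, abs=0.002)
        assert sc.sc_max_uv[0] == pytest.approx(30.0, rel=0.10)  # <4 Hz filter trims ~7%

    def test_zero_signal(self):
        sc = slow_component(make_epochs(np.zeros((2, 2, 5000))))
        assert sc.spontaneous_rms_uv == 0.0
        assert sc.evoked_rms_uv == 0.0
        assert np.all(sc.sc_max_uv == 0.0)


def constructed_pm(series_by_channel, n_f=40, rate=500.0, t0=-0.55, n_t=700):
    """PowerMap whose HF band mean equals the given per-channel series."""
    n_ch = len(series_by_channel)
    vals = np.zeros((n_ch, n_f, n_t))
    freqs = np.arange(1.0, n_f + 1)
    hf = (freqs >= 20) & (freqs <= 40)
    for ch, series in enumerate(series_by_channel):
        vals[ch, hf, :] = np.asarray(series)[None, :]
    return tfr.PowerMap(
        values=vals, frequencies=freqs,
        time_axis=t0 + np.arange(n_t) / rate, rate=rate,
        channel_labels=[f"C{i}" for i in range(n_ch)], baseline=(-0.5, -0.2),
    )


class TestOffPeriod:
    def test_rectangular_suppression_recovered_exactly(self):
        t0, rate, n_t = -0.55, 500.0, 700
        t = t0 + np.arange(n_t) / rate
        series = np.where((t >= 0.08 - 1e-9) & (t < 0.18 - 1e-9), -1.0, 0.0)
        pm = constructed_pm([series])
        off = detect_hf_suppression(pm, 0)
        assert off.detected
        assert off.start_s == pytest.approx(0.08, abs=1e-6)
        assert off.end_s == pytest.approx(0.18, abs=1e-6)
        assert off.min_db == -1.0
        assert off.mean_hf_db == pytest.approx(-1.0)
        # flat plateau: the minimum ties everywhere, argmin takes the first
        assert off.start_s <= off.min_latency_s < off.end_s

    def test_nonnegative_series_not_detected(self):
        pm = constructed_pm([np.ones(700) * 0.5])
        off = detect_hf_suppression(pm, 0)
        assert not off.detected
        assert np.isnan(off.start_s) and np.isnan(off.end_s)

    def test_planted_off_period_recovered(self):
        # background-only session with a -1 dB suppression planted 0.08-0.18 s
        starts, ends, fracs = [], [], []
        for seed in (5, 6):
            ep, _ = syn.simulate_session(
                syn.template("noise", off_depth_db=-1.0), seed=seed)
            tf = tfr.morlet_tf(ep, crop=(-0.55, 0.85))
            pm = tfr.bootstrap_mask_power(tf, seed=50 + seed,
                                          bands=[tfr.BANDS["HF"]])
            summ = off_period_summary(
                [detect_hf_suppression(pm, ch) for ch in range(16)])
            starts.append(summ["start_s"])
            ends.append(summ["end_s"])
            fracs.append(summ["fraction_detected"])
        assert np.mean(fracs) > 0.3
        assert abs(np.mean(starts) - 0.08) <= 0.02
        assert abs(np.mean(ends) - 0.18) <= 0.02

    def test_wake_like_yields_no_suppression(self):
        ep, _ = syn.simulate_session(syn.template("wake"), seed=21)
        tf = tfr.morlet_tf(ep, crop=(-0.55, 0.85))
        pm = tfr.bootstrap_mask_power(tf, seed=210, bands=[tfr.BANDS["HF"]])
        summ = off_period_summary(
            [detect_hf_suppression(pm, ch) for ch in range(16)])
        assert summ["fraction_detected"] <= 0.1
        assert summ["mean_hf_db"] > 0


class TestLateHF:
    def test_all_masked_probability_zero(self):
        late = detect_late_hf(constructed_pm([np.zeros(700)] * 3))
        assert late.probability == 0.0
        assert np.all(np.isnan(late.onsets_s))

    def test_uniform_positive_onset(self):
        t0, rate, n_t = -0.55, 500.0, 700
        t = t0 + np.arange(n_t) / rate
        series = np.where(t >= 0.3 - 1e-9, 1.0, 0.0)
        late = detect_late_hf(constructed_pm([series] * 2))
        assert late.probability == 1.0
        assert np.allclose(late.onsets_s, 0.3, atol=1e-6)

    def test_ketamine_like_tracks_planted_channels(self):
        ep, gt = syn.simulate_session(syn.template("ketamine"), seed=31)
        tf = tfr.morlet_tf(ep, crop=(-0.55, 0.85))
        pm = tfr.bootstrap_mask_power(tf, seed=310, bands=[tfr.BANDS["HF"]])
        late = detect_late_hf(pm)
        planted = float(gt["late_hf_flags"].mean())
        assert abs(late.probability - planted) <= 1.0 / 16 + 1e-9


class TestLFFeatures:
    def test_zero_map(self):
        lf = lf_features(constructed_pm([np.zeros(700)]),
                         band=(20, 40))  # use the populated rows
        assert lf.mean_db_channels == 0.0
        assert np.all(np.isnan(lf.peak_latency_s))

    def test_single_bump_latency_and_bruteforce(self):
        t0, rate, n_t = -0.55, 500.0, 700
        t = t0 + np.arange(n_t) / rate
        series = np.exp(-((t - 0.2) ** 2) / (2 * 0.03**2))
        pm = constructed_pm([series])
        lf = lf_features(pm, band=(20, 40))
        assert lf.peak_latency_s[0] == pytest.approx(0.2, abs=2e-3)
        sl = pm.slice((0.0, 0.6))
        brute = pm.time_axis[sl][np.argmax(series[sl])]
        assert abs(lf.peak_latency_s[0] - brute) <= 1.0 / rate
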