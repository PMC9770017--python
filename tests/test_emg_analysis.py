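import numpy as np
import pytest

from quadgait.emg_analysis import (bandpass_filter, burst_metrics,
                                   detect_bursts, envelope)

RATE = 5000.0


def _sine(freq, dur=2.0, amp=1.0):
    t = np.arange(int(dur * RATE)) / RATE
    return t, amp * np.sin(2 * np.pi * freq * t)


def test_bandpass_kills_dc():
    x = np.ones(10000)
    y = bandpass_filter(x, RATE)
    assert np.max(np.abs(y[2000:-2000])) < 1e-6


def test_bandpass_passes_300hz_within_5pct():
    t, x = _sine(300.0)
    y = bandpass_filter(x, RATE)
    mid = slice(2000, -2000)
    assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.05)


def test_bandpass_attenuates_5hz_by_20db():
    t, x = _sine(5.0)
    y = bandpass_filter(x, RATE)
    mid = slice(2000, -2000)
    assert np.max(np.abs(y[mid])) < 0.1


def test_bandpass_rejects_low_rate():
    with pytest.raises(ValueError):
        bandpass_filter(np.zeros(100), rate=1500.0)


def test_envelope_zero_and_linearity():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20000)
    assert np.allclose(envelope(np.zeros(5000), RATE), 0.0)
    e1 = envelope(x, RATE)
    e3 = envelope(3.0 * x, RATE)
    np.testing.assert_allclose(e3, 3.0 * e1, rtol=1e-9)


def test_envelope_tracks_modulation():
    rng = np.random.default_rng(1)
    t = np.arange(int(10 * RATE)) / RATE
    mod = 1.0 + 0.8 * np.sin(2 * np.pi * 1.0 * t)
    carrier = bandpass_filter(rng.normal(size=t.size), RATE)
    env = envelope(mod * carrier, RATE)
    mid = slice(5000, -5000)
    r = np.corrcoef(env[mid], mod[mid])[0, 1]
    assert r > 0.95


def _gated_signal(gates, dur=30.0, amp=1.0, snr=20.0, seed=2):
    rng = np.random.default_rng(seed)
    t = np.arange(int(dur * RATE)) / RATE
    env = np.zeros_like(t)
    for a, b in gates:
        sel = (t >= a) & (t < b)
        tau = (t[sel] - a) / (b - a)
        ramp = np.minimum(1.0, np.minimum(tau, 1 - tau) / 0.05)
        env[sel] = amp * ramp
    carrier = bandpass_filter(rng.normal(size=t.size), RATE)
    carrier /= np.std(carrier)
    noise = bandpass_filter(rng.normal(size=t.size), RATE)
    noise /= np.std(noise)
    return t, env * carrier + (amp / snr) * noise


def test_flat_envelope_has_no_bursts():
    rng = np.random.default_rng(3)
    t = np.arange(int(5 * RATE)) / RATE
    x = bandpass_filter(rng.normal(size=t.size), RATE)
    env = envelope(x, RATE)
    wins = [(0.5, 1.5), (2.0, 3.0)]
    found = detect_bursts(t, env, RATE, wins)
    assert all(b is None for b in found)


def test_bursts_found_at_gate_times_within_10ms():
    gates = [(1.0 + i, 1.4 + i) for i in range(25)]
    t, x = _gated_signal(gates)
    env = envelope(bandpass_filter(x, RATE), RATE)
    wins = [(0.7 + i, 1.7 + i) for i in range(25)]
    found = detect_bursts(t, env, RATE, wins)
    hits = 0
    for (a, b), det in zip(gates, found):
        assert det is not None
        hits += abs(det[0] - a) < 0.010 and abs(det[1] - b) < 0.010
    assert hits >= 0.95 * len(gates)


def test_longest_burst_retained_per_window():
    gates = [(1.0, 1.1), (1.5, 1.9)] + [(3.0 + i, 3.4 + i) for i in range(10)]
    t, x = _gated_signal(gates)
    env = envelope(bandpass_filter(x, RATE), RATE)
    found = detect_bursts(t, env, RATE, [(0.5, 2.5)])
    assert found[0] is not None
    on, off = found[0]
    assert abs(on - 1.5) < 0.02 and abs(off - 1.9) < 0.02


def test_burst_metrics_constant_amplitude():
    t = np.arange(int(2 * RATE)) / RATE
    rect = np.full_like(t, 0.7)
    m = burst_metrics(t, rect, (0.5, 1.2))
    assert m.mean_amplitude == pytest.approx(0.7)
    assert m.duration == pytest.approx(0.7)


def test_normalization_identity_and_scale_invariance():
    rng = np.random.default_rng(4)
    t = np.arange(int(2 * RATE)) / RATE
    rect = np.abs(rng.normal(size=t.size))
    m = burst_metrics(t, rect, (0.2, 0.8), control_mean=None)
    same = burst_metrics(t, rect, (0.2, 0.8), control_mean=m.mean_amplitude)
    assert same.normalized_amplitude == pytest.approx(100.0)
    scaled = burst_metrics(t, 5.0 * rect, (0.2, 0.8),
                           control_mean=5.0 * m.mean_amplitude)
    assert scaled.normalized_amplitude == pytest.approx(100.0)


def test_mean_amplitude_invariant_to_time_reversal():
    rng = np.random.default_rng(5)
    t = np.arange(int(1 * RATE)) / RATE
    rect = np.abs(rng.normal(size=t.size))
    fwd = burst_metrics(t, rect, (0.0, 1.0 - 1 / RATE)).mean_amplitude
    rev = burst_metrics(t, rect[::-1], (1 / RATE, 1.0)).mean_amplitude
    assert fwd == pytest.approx(rev, rel=1e-3)


def test_zero_control_mean_rejected():
    t = np.arange(1000) / RATE
    rect = np.abs(np.sin(t))
    with pytest.raises(ValueError):
        burst_metrics(t, rect, (0.0, 0.1), control_mean=0.0)
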