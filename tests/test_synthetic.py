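import numpy as np
import pytest

from quadgait.io_core import SessionConfig, toe_marker
from quadgait.gait_events import detect_cycles
from quadgait.spatiotemporal import joint_angle, support_periods
from quadgait.synthetic import (build_footfall_schedule, generate_session,
                                load_paper_effects, plan_stimulus_cycles)
from quadgait.synthetic.kinematics import (hindlimb_angle_waveforms,
                                           prescribed_hip_angle,
                                           toe_trajectory)
from quadgait.synthetic.emg import gate_windows
from quadgait.emg_analysis import bandpass_filter, detect_bursts, envelope


def test_schedule_direct_construction():
    s = build_footfall_schedule(cycle_period=1.0, duty_factor=0.65, n_cycles=5)
    ev = s.events["ipsi_hind"]
    for k in range(5):
        assert ev[k, 0] == pytest.approx(k)
        assert ev[k, 1] == pytest.approx(k + 0.65)


@pytest.mark.parametrize("duty", [0.0, 1.0, 1.2, -0.1])
def test_schedule_rejects_bad_duty(duty):
    with pytest.raises(ValueError):
        build_footfall_schedule(duty_factor=duty)


def test_canonical_schedule_has_eight_support_periods():
    """The default walk decomposes into 8 alternating double/triple periods."""
    s = build_footfall_schedule(cycle_period=1.0, duty_factor=0.65, n_cycles=6)
    periods = support_periods(s.events, (2.0, 3.0))
    assert len(periods) == 8
    sizes = [len(p.limb_set) for p in periods]
    assert sizes == [3, 2, 3, 2, 3, 2, 3, 2]


def test_timing_jitter_does_not_accumulate(rng):
    s = build_footfall_schedule(cycle_period=1.0, n_cycles=200,
                                timing_jitter_sigma=0.002, rng=rng)
    onsets = s.events["ipsi_hind"][:, 0]
    drift = onsets - np.arange(onsets.size)
    assert np.abs(drift).max() < 0.01  # a few jitter sigmas, not a random walk


def test_fixed_seed_reproduces_session_byte_identically(tmp_path):
    from quadgait.io_core import write_marker_csv

    cfg = SessionConfig(n_animals=1, cycles_per_animal=40, stimuli_per_phase=1,
                        seed=77)
    paths = []
    for i in range(2):
        sess = generate_session(cfg, with_emg=False)
        p = tmp_path / f"m{i}.csv"
        write_marker_csv(sess.animals[0].markers, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_zero_noise_toe_kinematics(small_clean_session):
    rec = small_clean_session.animals[0]
    plan = rec.plan
    a = rec.params
    ev = plan.events["ipsi_hind"]
    k = 10
    t_mid = 0.5 * (ev[k, 0] + ev[k, 1])
    xy = toe_trajectory(plan, "ipsi_hind", np.array([t_mid, ev[k, 0], ev[k, 1]]))
    assert xy[0, 1] == pytest.approx(0.0, abs=1e-12)  # on the belt mid-stance
    # horizontal displacement over stance = belt speed x stance duration
    assert xy[1, 0] - xy[2, 0] == pytest.approx(
        a.belt_speed * (ev[k, 1] - ev[k, 0]), abs=1e-12)


def test_zero_noise_swing_apex_equals_configured(small_clean_session):
    rec = small_clean_session.animals[0]
    plan = rec.plan
    ev = plan.events["contra_hind"]
    k = 8
    tt = np.linspace(ev[k, 1], ev[k + 1, 0], 2001)
    y = toe_trajectory(plan, "contra_hind", tt)[:, 1]
    assert y.max() == pytest.approx(rec.params.swing_apex, rel=1e-9)


def test_marker_chain_angles_match_prescription(small_clean_session):
    """Angles recomputed from generated markers equal the prescribed waveforms."""
    rec = small_clean_session.animals[0]
    m = rec.markers
    w = hindlimb_angle_waveforms(rec.plan, "ipsi_hind", m.time)
    knee = joint_angle(m.xy("right", "trochanter"), m.xy("right", "knee"),
                       m.xy("right", "malleolus"))
    ankle = joint_angle(m.xy("right", "knee"), m.xy("right", "malleolus"),
                        m.xy("right", "mtp"))
    hip = joint_angle(m.xy("right", "iliac_crest"), m.xy("right", "trochanter"),
                      m.xy("right", "knee"))
    np.testing.assert_allclose(knee, w["knee"], atol=1e-6)
    np.testing.assert_allclose(ankle, w["ankle"], atol=1e-6)
    np.testing.assert_allclose(hip, prescribed_hip_angle(w["theta_thigh"]),
                               atol=1e-6)


def test_identity_profile_leaves_cycle_unperturbed():
    from quadgait.io_core import PerturbationProfile

    cfg = SessionConfig(n_animals=1, cycles_per_animal=60, stimuli_per_phase=2,
                        seed=3)
    ident = {p: PerturbationProfile.identity() for p in cfg.phase_targets}
    sess = generate_session(cfg, profiles=ident, noise=False, with_emg=False)
    plan = sess.animals[0].plan
    ev = plan.events["ipsi_hind"]
    durations = np.diff(ev[:, 0])
    np.testing.assert_allclose(durations, durations[0], rtol=1e-12)
    assert np.all(plan.apex["ipsi_hind"] == plan.apex["ipsi_hind"][0])


def test_injected_swing_multiplier_recovered_exactly_at_zero_noise(
        small_clean_session):
    """Measured ipsi swing ratio stim/control equals the injected multiplier."""
    rec = small_clean_session.animals[0]
    profiles = load_paper_effects()
    mult = profiles["mid_swing"].swing_multiplier["ipsi_hind"]
    t = rec.markers.time
    xy = rec.markers.xy(*toe_marker("right", "hind"))
    cycles = detect_cycles(t, xy, "ipsi_hind")
    onsets = np.array([c.stance_onset for c in cycles])
    ratios = []
    for tr in rec.plan.truth:
        if tr["phase"] != "mid_swing":
            continue
        i = int(np.searchsorted(onsets, tr["t_onset"], side="right")) - 1
        ratios.append(cycles[i].swing_duration / cycles[i - 1].swing_duration)
    assert ratios
    np.testing.assert_allclose(ratios, mult, rtol=5e-3)


def test_stimulus_plan_spacing_and_counts(rng):
    cfg = SessionConfig(seed=0)
    plan = plan_stimulus_cycles(cfg, rng)
    cycles = np.array([c for c, _ in plan])
    gaps = np.diff(cycles)
    assert np.all((gaps >= 5) & (gaps <= 6))
    phases = [p for _, p in plan]
    for p in cfg.phase_targets:
        assert phases.count(p) == cfg.stimuli_per_phase


def test_stimulus_plan_overflow_raises(rng):
    cfg = SessionConfig(cycles_per_animal=50, stimuli_per_phase=10, seed=0)
    with pytest.raises(ValueError, match="do not fit"):
        plan_stimulus_cycles(cfg, rng)


# ---------------------------------------------------------------------------
# EMG generator
# ---------------------------------------------------------------------------


def _emg_session(seed=21, **kw):
    cfg = SessionConfig(n_animals=1, cycles_per_animal=60, stimuli_per_phase=1,
                        seed=seed)
    return generate_session(cfg, with_emg=True, emg_muscles=("ST", "VL"), **kw)


def test_zero_gain_channel_has_no_bursts():
    sess = _emg_session()
    rec = sess.animals[0]
    rec.params.emg_amplitude["ST"] = 0.0
    from quadgait.synthetic.emg import synthesize_emg
    emg = synthesize_emg(rec.plan, rng=np.random.default_rng(5),
                         muscles=("ST",))
    sig = emg.channels[("right", "ST")]
    filt = bandpass_filter(sig, emg.rate)
    env = envelope(filt, emg.rate)
    ev = rec.plan.events["ipsi_hind"]
    wins = [(ev[i, 0], ev[i + 1, 0]) for i in range(20, 40)]
    bursts = detect_bursts(emg.time, env, emg.rate, wins)
    # pure baseline noise: no (or almost no) windows contain a real burst
    assert sum(b is not None for b in bursts) <= 2


def test_burst_count_matches_cycle_count():
    sess = _emg_session()
    rec = sess.animals[0]
    emg = rec.emg
    filt = bandpass_filter(emg.channels[("right", "VL")], emg.rate)
    env = envelope(filt, emg.rate)
    ev = rec.plan.events["contra_hind"] if False else rec.plan.events["ipsi_hind"]
    wins = [(ev[i, 0], ev[i + 1, 0]) for i in range(3, ev.shape[0] - 4)
            if ev[i + 1, 0] < emg.time[-1]]
    bursts = detect_bursts(emg.time, env, emg.rate, wins)
    found = sum(b is not None for b in bursts)
    assert found >= 0.95 * len(wins)


def test_doubling_envelope_gain_doubles_burst_amplitude():
    """Monte-Carlo over ~50 bursts: measured amplitude scales with gain."""
    from quadgait.emg_analysis import burst_metrics

    means = []
    for gain in (1.0, 2.0):
        sess = _emg_session(seed=31)
        rec = sess.animals[0]
        rec.params.emg_amplitude["ST"] = 1e-4 * gain
        from quadgait.synthetic.emg import synthesize_emg
        emg = synthesize_emg(rec.plan, rng=np.random.default_rng(9),
                             muscles=("ST",))
        filt = bandpass_filter(emg.channels[("right", "ST")], emg.rate)
        env = envelope(filt, emg.rate)
        ev = rec.plan.events["ipsi_hind"]
        wins = [(ev[i, 0], ev[i + 1, 0]) for i in range(3, 55)]
        bursts = detect_bursts(emg.time, env, emg.rate, wins)
        amps = [burst_metrics(emg.time, np.abs(filt), b).mean_amplitude
                for b in bursts if b is not None]
        assert len(amps) >= 50
        means.append(np.mean(amps))
    assert means[1] / means[0] == pytest.approx(2.0, rel=0.05)


def test_gate_windows_follow_schedule_and_gains():
    sess = _emg_session()
    plan = sess.animals[0].plan
    ext = gate_windows(plan, "ipsi_hind", "VL")
    flex = gate_windows(plan, "ipsi_hind", "ST")
    ev = plan.events["ipsi_hind"]
    assert ext[5][0] == pytest.approx(ev[5, 0])
    assert flex[5][0] == pytest.approx(ev[5, 1])
    with pytest.raises(ValueError):
        gate_windows(plan, "ipsi_hind", "XXX")
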