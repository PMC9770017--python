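import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quadgait.gait_events import GaitCycle
from quadgait.io_core import LIMB_ROLES
from quadgait.spatiotemporal import (SUPPORT_CATEGORIES, angle_summary,
                                     category_durations, joint_angle,
                                     max_height, step_length, stride_length,
                                     support_periods)
from quadgait.synthetic import build_footfall_schedule


def brute_force_support(intervals, window, resolution=1000):
    """Frame-wise limb-set labeling at 1 kHz, merged into runs (oracle)."""
    t0, t1 = window
    ts = t0 + (np.arange(int(np.ceil((t1 - t0) * resolution))) + 0.5) / resolution
    labels = []
    for t in ts:
        limbs = frozenset(
            r for r in LIMB_ROLES
            if np.any((intervals[r][:, 0] <= t) & (t < intervals[r][:, 1])))
        labels.append(limbs)
    runs = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    return [(lab, n / resolution) for lab, n in runs]


def test_all_limbs_down_gives_single_quad_period():
    iv = {r: np.array([[0.0, 10.0]]) for r in LIMB_ROLES}
    periods = support_periods(iv, (2.0, 3.0))
    assert len(periods) == 1
    assert periods[0].category == "quad"
    assert periods[0].duration == pytest.approx(1.0)


def test_no_stance_raises():
    iv = {r: np.array([[100.0, 101.0]]) for r in LIMB_ROLES}
    with pytest.raises(ValueError):
        support_periods(iv, (0.0, 1.0))


def test_support_tiles_cycle_window():
    s = build_footfall_schedule(1.1, 0.65, n_cycles=8)
    periods = support_periods(s.events, (2.2, 3.3))
    assert sum(p.duration for p in periods) == pytest.approx(1.1, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_support_decomposition_matches_brute_force(seed):
    """Sweep-line decomposition equals 1 kHz frame labeling on random walks."""
    rng = np.random.default_rng(seed)
    duty = {r: rng.uniform(0.45, 0.8) for r in LIMB_ROLES}
    offsets = {"ipsi_hind": 0.0}
    for r in ("contra_hind", "homo_fore", "diag_fore"):
        offsets[r] = rng.uniform(0.0, 0.999)
    T = rng.uniform(0.6, 1.4)
    s = build_footfall_schedule(T, duty, offsets, n_cycles=8)
    window = (3 * T, 4 * T)
    periods = support_periods(s.events, window)
    oracle = brute_force_support(s.events, window)
    got = {}
    for p in periods:
        got[p.category] = got.get(p.category, 0.0) + p.duration
    want = {}
    for lab, dur in oracle:
        from quadgait.spatiotemporal import support_category
        cat = support_category(lab)
        want[cat] = want.get(cat, 0.0) + dur
    for cat in set(got) | set(want):
        assert got.get(cat, 0.0) == pytest.approx(want.get(cat, 0.0), abs=5e-3)


def test_nine_categories_with_quad_substitution():
    cats = set()
    for diag_offset in (0.75, 0.60):
        s = build_footfall_schedule(
            1.0, 0.65, {"ipsi_hind": 0, "contra_hind": 0.5,
                        "homo_fore": 0.25, "diag_fore": diag_offset},
            n_cycles=6)
        cats |= {p.category for p in support_periods(s.events, (2.0, 3.0))}
    assert cats == set(SUPPORT_CATEGORIES)


def test_step_length_formula():
    t = np.arange(100) / 60.0
    x_lead = np.full(100, 0.05)
    x_trail = np.full(100, -0.07)
    assert step_length(t, x_lead, x_trail, 0.5) == pytest.approx(0.12)
    assert step_length(t, x_lead, x_lead, 0.5) == 0.0
    with pytest.raises(ValueError):
        step_length(t, x_lead, x_trail, 99.0)


def test_stride_length_formula_and_degenerate_swing():
    t = np.arange(0, 2.0, 1 / 60.0)
    x = np.interp(t, [0.0, 1.0, 2.0], [0.10, -0.30, 0.1])
    cyc = GaitCycle("x", 0, 0.0, 0.5, 1.0)
    got = stride_length(cyc, t, x, belt_speed=0.4)
    assert got == pytest.approx(0.2 + 0.5 * 0.4, abs=1e-6)


def test_joint_angle_examples():
    prox = np.array([[0.0, 1.0]])
    vert = np.array([[0.0, 0.0]])
    dist = np.array([[1.0, 0.0]])
    assert joint_angle(prox, vert, dist)[0] == pytest.approx(90.0)
    collinear = joint_angle(np.array([[0, 1.0]]), np.array([[0, 0.0]]),
                            np.array([[0, -1.0]]))
    assert collinear[0] == pytest.approx(180.0)
    degenerate = joint_angle(vert, vert, dist)
    assert np.isnan(degenerate[0])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(-np.pi, np.pi), st.floats(-5, 5), st.floats(-5, 5))
def test_joint_angle_rigid_motion_invariance(theta, dx, dy):
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(3, 8, 2))
    base = joint_angle(pts[0], pts[1], pts[2])
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    moved = [p @ rot.T + [dx, dy] for p in pts]
    np.testing.assert_allclose(joint_angle(*moved), base, atol=1e-8)


def test_angle_summary_constant_series():
    t = np.arange(0, 2.0, 1 / 60.0)
    ang = np.full_like(t, 123.0)
    cyc = GaitCycle("x", 0, 0.2, 0.8, 1.3)
    s = angle_summary(t, ang, cyc, "knee")
    assert s.max == s.min == s.at_contact == s.at_liftoff == 123.0
    assert s.excursion == 0.0


def test_angle_summary_invalid_when_mostly_missing():
    t = np.arange(0, 2.0, 1 / 60.0)
    ang = np.full_like(t, np.nan)
    ang[:10] = 100.0
    cyc = GaitCycle("x", 0, 0.2, 0.8, 1.3)
    assert not angle_summary(t, ang, cyc).valid


def test_max_height_finds_apex():
    t = np.arange(0, 1.0, 1 / 60.0)
    y = 0.03 * np.sin(np.pi * t) ** 2
    cyc = GaitCycle("x", 0, 0.0, 0.3, 0.999)
    assert max_height(t, y, cyc, smooth=False) == pytest.approx(0.03, rel=1e-3)


def test_treadmill_conservation_on_noiseless_cycles(small_clean_session):
    """stride = belt speed x cycle duration, to numerical precision."""
    from quadgait.gait_events import detect_cycles
    from quadgait.io_core import limb_roles_for, toe_marker

    rec = small_clean_session.animals[0]
    t = rec.markers.time
    v = rec.params.belt_speed
    for role, (side, girdle) in limb_roles_for("right").items():
        xy = rec.markers.xy(*toe_marker(side, girdle))
        for c in detect_cycles(t, xy, role):
            sl = stride_length(c, t, xy[:, 0], v)
            assert abs(sl - v * c.cycle_duration) < 1e-6


def test_category_durations_sums_recurrences():
    from quadgait.spatiotemporal import SupportPeriod

    p = [SupportPeriod(0.0, 0.1, frozenset({"contra_hind", "homo_fore"}),
                       "contra_homo"),
         SupportPeriod(0.5, 0.2, frozenset({"contra_hind", "homo_fore"}),
                       "contra_homo")]
    assert category_durations(p)["contra_homo"] == pytest.approx(0.3)
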