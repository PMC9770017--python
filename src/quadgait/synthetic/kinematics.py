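"""Marker-trajectory synthesis by forward kinematics from a session plan.

Toe markers are prescribed directly from the footfall schedule: during stance
the toe rides the belt backward at belt speed from its landing position;
during swing it travels forward along a minimum-jerk profile while its height
follows a half-sine bell with a per-swing apex. Proximal markers are placed
by a sagittal kinematic chain (pelvis->thigh->shank->foot; shoulder->arm->
forearm) driven by prescribed segment-orientation and joint-angle waveforms.
The chain and the prescribed toe are not coupled — the chain carries the
joint-angle ground truth, the toe carries the contact/step ground truth —
which is a deliberate simplification of a synthetic generator, not a model
of limb mechanics.
"""

from __future__ import annotations

import numpy as np

from ..io_core import MarkerTrajectories, limb_roles_for
from .perturb import FORE_GIRDLE_OFFSET, SessionPlan

# hindlimb angle-waveform constants (deg)
HIP_SWEEP = 20.0         # thigh orientation amplitude about vertical
KNEE_BASE = 115.0        # knee joint angle outside the swing flexion
KNEE_STANCE_YIELD = 5.0
KNEE_SWING_FLEX = 30.0   # default swing flexion depth (knee min = base - flex)
ANKLE_BASE = 110.0
ANKLE_STANCE_YIELD = 8.0
ANKLE_SWING_FLEX = 25.0
ILIAC_ANGLE = 25.0       # iliac crest direction from vertical, deg
ILIAC_LENGTH = 0.05      # m
HIP_BOB = 0.004          # m, vertical hip oscillation amplitude

# forelimb constants
#: vertical paw speed during the terminal approach/departure segments, m/s
TOUCHDOWN_SPEED = 0.35
#: duration of the linear lift-off/touchdown segments, s
TERMINAL_SEGMENT = 0.06

ARM_SWEEP = 15.0
ELBOW_BASE = 140.0
ELBOW_STANCE_YIELD = 10.0
ELBOW_SWING_FLEX = 25.0


def minimum_jerk(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _seg(theta_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vector of a segment at angle theta from vertical-down (+ anterior)."""
    th = np.deg2rad(theta_deg)
    return np.sin(th), -np.cos(th)


def _cycle_phase(events: np.ndarray, t: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame cycle index, phase in [0,1), duty of that cycle, swing s."""
    onsets = events[:, 0]
    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, events.shape[0] - 2)
    on = onsets[idx]
    off = events[idx, 1]
    nxt = onsets[idx + 1]
    u = (t - on) / (nxt - on)
    duty = (off - on) / (nxt - on)
    in_swing = t >= off
    s = np.where(in_swing, (t - off) / np.maximum(nxt - off, 1e-12), 0.0)
    return idx, u, duty, s


def toe_trajectory(plan: SessionPlan, role: str, t: np.ndarray
                   ) -> np.ndarray:
    """(n, 2) toe x/y for one limb over the given times."""
    ev = plan.events[role]
    v = plan.animal.belt_speed
    idx, _, _, s = _cycle_phase(ev, t)
    on = ev[idx, 0]
    off = ev[idx, 1]
    td = plan.td_x[role][idx]
    td_next = plan.td_x[role][np.minimum(idx + 1, ev.shape[0] - 1)]
    apex = plan.apex[role][idx]
    in_swing = t >= off
    x_stance = td - v * (t - on)
    x_off = td - v * (off - on)
    x_swing = x_off + (td_next - x_off) * minimum_jerk(s)
    # flat-topped bell with fixed-slope linear segments at lift-off and
    # touchdown: the terminal vertical speed of the paw is a property of the
    # gait, not of how high the paw was lifted or how long the swing lasted
    sc = np.clip(s, 0, 1)
    swing_dur = np.maximum(ev[np.minimum(idx + 1, ev.shape[0] - 1), 0] - off,
                           1e-9)
    y_j = np.minimum(TOUCHDOWN_SPEED * TERMINAL_SEGMENT, 0.6 * apex)
    t_j = y_j / TOUCHDOWN_SPEED  # duration of each linear segment
    u_sw = sc * swing_dur  # time since lift-off
    r_sw = (1.0 - sc) * swing_dur  # time to touchdown
    mid_span = np.maximum(swing_dur - 2.0 * t_j, 1e-9)
    s_mid = np.clip((u_sw - t_j) / mid_span, 0.0, 1.0)
    y_mid = y_j + (apex - y_j) * np.sqrt(np.sin(np.pi * s_mid))
    y_sw = np.where(np.minimum(u_sw, r_sw) <= t_j,
                    TOUCHDOWN_SPEED * np.minimum(u_sw, r_sw), y_mid)
    y = np.where(in_swing, y_sw, 0.0)
    x = np.where(in_swing, x_swing, x_stance)
    return np.column_stack([x, y])


def hindlimb_angle_waveforms(plan: SessionPlan, role: str, t: np.ndarray
                             ) -> dict[str, np.ndarray]:
    """Prescribed thigh orientation and knee/ankle joint angles (deg)."""
    ev = plan.events[role]
    idx, u, duty, s = _cycle_phase(ev, t)
    in_swing = s > 0
    up = np.clip(u / np.maximum(duty, 1e-9), 0.0, 1.0)
    theta1 = np.where(in_swing,
                      -HIP_SWEEP * np.cos(np.pi * s),
                      HIP_SWEEP * np.cos(np.pi * up))
    knee_flex = np.full_like(t, KNEE_SWING_FLEX)
    ankle_flex = np.full_like(t, ANKLE_SWING_FLEX)
    if role == "ipsi_hind" and plan.flex_mult:
        for k, mults in plan.flex_mult.items():
            sel = idx == k
            if not np.any(sel):
                continue
            if "knee" in mults:
                knee_flex[sel] = KNEE_BASE - mults["knee"] * (KNEE_BASE - KNEE_SWING_FLEX)
            if "ankle" in mults:
                ankle_flex[sel] = ANKLE_BASE - mults["ankle"] * (ANKLE_BASE - ANKLE_SWING_FLEX)
    knee = np.where(in_swing,
                    KNEE_BASE - knee_flex * np.sin(np.pi * s) ** 2,
                    KNEE_BASE - KNEE_STANCE_YIELD * np.sin(np.pi * up))
    ankle = np.where(in_swing,
                     ANKLE_BASE - ankle_flex * np.sin(np.pi * s) ** 2,
                     ANKLE_BASE - ANKLE_STANCE_YIELD * np.sin(np.pi * up))
    return {"theta_thigh": theta1, "knee": knee, "ankle": ankle, "u": u}


def prescribed_hip_angle(theta_thigh: np.ndarray) -> np.ndarray:
    """Included iliac-trochanter-knee angle implied by the thigh orientation."""
    # iliac vector points up-anterior at ILIAC_ANGLE; thigh down at theta
    v1 = np.array([np.sin(np.deg2rad(ILIAC_ANGLE)), np.cos(np.deg2rad(ILIAC_ANGLE))])
    ux, uy = _seg(theta_thigh)
    cosang = np.clip(v1[0] * ux + v1[1] * uy, -1.0, 1.0)
    return np.rad2deg(np.arccos(cosang))


def _hind_chain(plan: SessionPlan, role: str, t: np.ndarray
                ) -> dict[str, np.ndarray]:
    a = plan.animal
    w = hindlimb_angle_waveforms(plan, role, t)
    troch_y = a.hip_height + HIP_BOB * np.sin(2 * np.pi * w["u"])
    troch = np.column_stack([np.zeros_like(t), troch_y])
    iliac = troch + ILIAC_LENGTH * np.array(
        [np.sin(np.deg2rad(ILIAC_ANGLE)), np.cos(np.deg2rad(ILIAC_ANGLE))])
    th1 = w["theta_thigh"]
    kx, ky = _seg(th1)
    knee = troch + a.thigh * np.column_stack([kx, ky])
    th2 = th1 - (180.0 - w["knee"])
    sx, sy = _seg(th2)
    mall = knee + a.shank * np.column_stack([sx, sy])
    th3 = th2 + (180.0 - w["ankle"])
    fx, fy = _seg(th3)
    mtp = mall + a.foot * np.column_stack([fx, fy])
    return {"iliac_crest": iliac, "trochanter": troch, "knee": knee,
            "malleolus": mall, "mtp": mtp}


def _fore_chain(plan: SessionPlan, role: str, t: np.ndarray,
                toe: np.ndarray) -> dict[str, np.ndarray]:
    a = plan.animal
    ev = plan.events[role]
    _, u, duty, s = _cycle_phase(ev, t)
    in_swing = s > 0
    up = np.clip(u / np.maximum(duty, 1e-9), 0.0, 1.0)
    scap = np.column_stack([
        np.full_like(t, FORE_GIRDLE_OFFSET),
        np.full_like(t, a.shoulder_height + 0.02)])
    hum = scap + np.array([0.02, -0.03])
    th1 = np.where(in_swing, -ARM_SWEEP * np.cos(np.pi * s),
                   ARM_SWEEP * np.cos(np.pi * up))
    ex, ey = _seg(th1)
    elbow = hum + a.arm * np.column_stack([ex, ey])
    beta = np.where(in_swing,
                    ELBOW_BASE - ELBOW_SWING_FLEX * np.sin(np.pi * s) ** 2,
                    ELBOW_BASE - ELBOW_STANCE_YIELD * np.sin(np.pi * up))
    th2 = th1 - (180.0 - beta)
    wx, wy = _seg(th2)
    wrist = elbow + a.forearm * np.column_stack([wx, wy])
    mcp = 0.7 * wrist + 0.3 * toe + np.array([0.0, 0.005])
    return {"scapula": scap, "humerus": hum, "elbow": elbow,
            "wrist": wrist, "mcp": mcp}


def synthesize_markers(plan: SessionPlan, frame_rate: float = 60.0,
                       rng: np.random.Generator | None = None
                       ) -> MarkerTrajectories:
    """Render the plan into a full marker set, with Gaussian jitter last."""
    a = plan.animal
    n_frames = int(round(plan.duration * frame_rate))
    t = np.arange(n_frames) / frame_rate
    roles = limb_roles_for(plan.stim_side)
    landmarks: dict[tuple[str, str], np.ndarray] = {}
    for role, (side, girdle) in roles.items():
        toe = toe_trajectory(plan, role, t)
        if girdle == "hind":
            chain = _hind_chain(plan, role, t)
            chain["hind_toe"] = toe
        else:
            chain = _fore_chain(plan, role, t, toe)
            chain["fore_toe"] = toe
        for name, arr in chain.items():
            landmarks[(side, name)] = np.array(arr, dtype=float)
    if a.marker_jitter_sigma > 0:
        if rng is None:
            raise ValueError("marker jitter requires an rng")
        for key in landmarks:
            landmarks[key] = landmarks[key] + rng.normal(
                0.0, a.marker_jitter_sigma, landmarks[key].shape)
    return MarkerTrajectories(time=t, landmarks=landmarks,
                              frame_rate=frame_rate, animal=a.name,
                              belt_speed=a.belt_speed)
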