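"""Support periods, step/stride lengths, joint angles and marker heights.

A *support period* is a maximal interval during which the set of limbs in
stance is constant. In a symmetric walk a cycle decomposes into eight
periods alternating between triple and double support; when the diagonal
forelimb lands before the ipsilateral hindlimb lifts, the short diagonal
double support is replaced by a quadrupedal support period, giving nine
distinct categories overall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .gait_events import GaitCycle
from .io_core import LIMB_ROLES

#: the nine support categories: four doubles, four triples, quad
SUPPORT_CATEGORIES = (
    "ipsi_homo", "ipsi_diag", "contra_homo", "contra_diag",
    "triple_no_ipsi", "triple_no_contra", "triple_no_homo", "triple_no_diag",
    "quad",
)

_SHORT = {"ipsi_hind": "ipsi", "contra_hind": "contra",
          "homo_fore": "homo", "diag_fore": "diag"}


def support_category(limb_set: frozenset[str]) -> str:
    """Category label for a set of limbs in stance; 'other' if atypical."""
    if len(limb_set) == 4:
        return "quad"
    if len(limb_set) == 3:
        (missing,) = set(LIMB_ROLES) - limb_set
        return f"triple_no_{_SHORT[missing]}"
    if len(limb_set) == 2:
        shorts = {_SHORT[r] for r in limb_set}
        for cat in ("ipsi_homo", "ipsi_diag", "contra_homo", "contra_diag"):
            if set(cat.split("_")) == shorts:
                return cat
    return "other"


@dataclass(frozen=True)
class SupportPeriod:
    start: float
    duration: float
    limb_set: frozenset[str]
    category: str

    @property
    def end(self) -> float:
        return self.start + self.duration


def support_periods(stance_intervals: dict[str, np.ndarray],
                    window: tuple[float, float]) -> list[SupportPeriod]:
    """Decompose a cycle window into maximal constant-limb-set periods.

    ``stance_intervals`` maps each limb role to an (n, 2) array of stance
    [onset, offset) intervals covering the window's neighbourhood.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive length")
    bounds = {t0, t1}
    for role in LIMB_ROLES:
        iv = np.asarray(stance_intervals[role], float).reshape(-1, 2)
        for a, b in iv:
            if a > t0 and a < t1:
                bounds.add(float(a))
            if b > t0 and b < t1:
                bounds.add(float(b))
    edges = np.array(sorted(bounds))

    def in_stance(role: str, t: float) -> bool:
        iv = np.asarray(stance_intervals[role], float).reshape(-1, 2)
        return bool(np.any((iv[:, 0] <= t) & (t < iv[:, 1])))

    periods: list[SupportPeriod] = []
    any_stance = False
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        limbs = frozenset(r for r in LIMB_ROLES if in_stance(r, mid))
        any_stance = any_stance or bool(limbs)
        if periods and periods[-1].limb_set == limbs:
            prev = periods.pop()
            periods.append(SupportPeriod(prev.start, b - prev.start, limbs,
                                         prev.category))
        else:
            periods.append(SupportPeriod(float(a), float(b - a), limbs,
                                         support_category(limbs)))
    if not any_stance:
        raise ValueError("no limb is ever in stance within the window")
    return periods


def category_durations(periods: list[SupportPeriod]) -> dict[str, float]:
    """Summed duration per support category (recurrences within a cycle add)."""
    out = {cat: 0.0 for cat in SUPPORT_CATEGORIES}
    out["other"] = 0.0
    for p in periods:
        out[p.category] += p.duration
    return out


# ---------------------------------------------------------------------------
# Lengths
# ---------------------------------------------------------------------------


def step_length(time: np.ndarray, x_leading: np.ndarray,
                x_trailing: np.ndarray, t_onset: float) -> float:
    """Horizontal separation of homologous toes at the leading limb's contact."""
    time = np.asarray(time, float)
    if not time[0] <= t_onset <= time[-1]:
        raise ValueError("stance onset outside the trajectory span")
    xl = float(np.interp(t_onset, time, x_leading))
    xt = float(np.interp(t_onset, time, x_trailing))
    return abs(xl - xt)


def _stance_line_sample(time: np.ndarray, x: np.ndarray, t: float,
                        lo: float, hi: float) -> float:
    """x at time t, extrapolated along the local stance line.

    During stance the toe rides the belt, so x is linear in t; sampling on a
    short line fit through frames strictly inside [lo, hi] avoids mixing in
    swing frames when t sits on a stance boundary.
    """
    inside = np.nonzero((time >= lo) & (time <= hi))[0]
    if inside.size < 2:
        return float(np.interp(t, time, x))
    if t - lo < hi - t:
        pick = inside[:2]
    else:
        pick = inside[-2:]
    t0, t1 = time[pick[0]], time[pick[1]]
    x0, x1 = x[pick[0]], x[pick[1]]
    return float(x0 + (x1 - x0) * (t - t0) / (t1 - t0))


def stride_length(cycle: GaitCycle, time: np.ndarray, toe_x: np.ndarray,
                  belt_speed: float) -> float:
    """Stance displacement plus belt travel during swing.

    On a treadmill the limb's progression during swing happens relative to
    the moving belt, so the swing contribution is swing duration times belt
    speed. Both endpoints are sampled on the stance line.
    """
    time = np.asarray(time, float)
    if not (time[0] <= cycle.stance_onset and cycle.stance_offset <= time[-1]):
        raise ValueError("cycle outside the trajectory span")
    x_on = _stance_line_sample(time, toe_x, cycle.stance_onset,
                               cycle.stance_onset, cycle.stance_offset)
    x_off = _stance_line_sample(time, toe_x, cycle.stance_offset,
                                cycle.stance_onset, cycle.stance_offset)
    return abs(x_on - x_off) + cycle.swing_duration * belt_speed


# ---------------------------------------------------------------------------
# Angles and heights
# ---------------------------------------------------------------------------


def joint_angle(proximal: np.ndarray, vertex: np.ndarray,
                distal: np.ndarray) -> np.ndarray:
    """Included angle (deg) at the vertex marker, frame by frame.

    Frames where either neighbour coincides with the vertex are NaN.
    """
    v1 = np.asarray(proximal, float) - np.asarray(vertex, float)
    v2 = np.asarray(distal, float) - np.asarray(vertex, float)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    bad = (n1 < 1e-12) | (n2 < 1e-12)
    n1 = np.where(bad, 1.0, n1)
    n2 = np.where(bad, 1.0, n2)
    cosang = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return np.where(bad, np.nan, ang)


@dataclass(frozen=True)
class AngleSummary:
    joint: str
    at_contact: float
    at_liftoff: float
    max: float
    min: float
    valid: bool = True

    @property
    def excursion(self) -> float:
        return self.max - self.min


def angle_summary(time: np.ndarray, angle: np.ndarray, cycle: GaitCycle,
                  joint: str = "") -> AngleSummary:
    """Extrema and event-sampled values of an angle series over one cycle."""
    time = np.asarray(time, float)
    angle = np.asarray(angle, float)
    sel = (time >= cycle.stance_onset) & (time < cycle.next_onset)
    win = angle[sel]
    n_bad = int(np.sum(~np.isfinite(win)))
    valid = win.size > 0 and n_bad <= 0.1 * win.size
    if not valid or np.all(~np.isfinite(win)):
        return AngleSummary(joint, np.nan, np.nan, np.nan, np.nan, valid=False)
    good = np.isfinite(angle)
    at_contact = float(np.interp(cycle.stance_onset, time[good], angle[good]))
    at_liftoff = float(np.interp(cycle.stance_offset, time[good], angle[good]))
    return AngleSummary(joint, at_contact, at_liftoff,
                        float(np.nanmax(win)), float(np.nanmin(win)),
                        valid=True)


def max_height(time: np.ndarray, y: np.ndarray, cycle: GaitCycle,
               smooth: bool = True) -> float:
    """Maximum marker height above the belt over one cycle window.

    A light Savitzky-Golay smoothing (window 5, order 2) suppresses the
    upward bias that frame-wise jitter adds to a maximum statistic.
    """
    time = np.asarray(time, float)
    y = np.asarray(y, float)
    if smooth and y.size >= 5:
        y = savgol_filter(y, 5, 2)
    sel = (time >= cycle.stance_onset) & (time < cycle.next_onset)
    if not np.any(sel):
        raise ValueError("cycle window contains no samples")
    return float(np.max(y[sel]))
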