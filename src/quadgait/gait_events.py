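"""Stance onset/offset detection and gait-cycle assembly from toe trajectories.

Stance onset is the start of a sustained paw-contact run, defined by the toe
height dropping below a threshold for a minimum number of frames. Stance
offset is the most caudal toe position within the stance run: on a treadmill
the paw travels backward with the belt during stance, so the x minimum marks
liftoff.

Both events are refined to sub-frame precision by default — a local linear
fit through the height-threshold crossing for onsets, and the intersection
of the stance line with the caudal plateau for offsets. ``refine=False``
reports events on the video frame grid instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EventParams:
    """Contact-detection parameters."""

    height_threshold: float = 0.005  # m
    min_contact_frames: int = 3
    refine: bool = True


@dataclass(frozen=True)
class GaitCycle:
    """One step cycle of one limb, delimited by successive stance onsets."""

    limb: str
    index: int
    stance_onset: float
    stance_offset: float
    next_onset: float

    def __post_init__(self) -> None:
        if not self.stance_onset < self.stance_offset < self.next_onset:
            raise ValueError(
                f"{self.limb} cycle {self.index}: require onset < offset < "
                f"next onset, got ({self.stance_onset}, {self.stance_offset}, "
                f"{self.next_onset})")

    @property
    def cycle_duration(self) -> float:
        return self.next_onset - self.stance_onset

    @property
    def stance_duration(self) -> float:
        return self.stance_offset - self.stance_onset

    @property
    def swing_duration(self) -> float:
        # defined as cycle minus stance so the identity holds exactly
        return self.cycle_duration - self.stance_duration

    @property
    def duty_factor(self) -> float:
        return self.stance_duration / self.cycle_duration

    def contains(self, t: float) -> bool:
        return self.stance_onset <= t < self.next_onset


def _contact_runs(contact: np.ndarray, min_frames: int) -> list[tuple[int, int]]:
    """Maximal [start, stop) index runs of contact lasting >= min_frames."""
    padded = np.concatenate([[False], contact, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    stops = np.nonzero(~padded[1:] & padded[:-1])[0]
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_frames]


def _crossing_time(time: np.ndarray, y: np.ndarray, f: int,
                   threshold: float) -> float:
    """Sub-frame threshold-crossing time within the bracketing frame pair.

    The descent through the contact threshold is steep (the paw lands with
    non-zero vertical velocity), so linear interpolation between the two
    frames spanning the threshold is accurate; fitting across more frames
    would mix in the much shallower upper part of the trajectory.
    """
    if f == 0:
        return float(time[0])
    y0, y1 = y[f - 1], y[f]
    if y0 <= y1:  # not descending; keep the frame time
        return float(time[f])
    t_star = time[f - 1] + (time[f] - time[f - 1]) * (y0 - threshold) / (y0 - y1)
    return float(np.clip(t_star, time[f - 1], time[f]))


def _descent_speed(y: np.ndarray, frames: list[int], threshold: float,
                   dt: float) -> float | None:
    """Terminal descent speed shared by a limb's touchdowns.

    Estimated from the last two airborne samples before each contact run —
    both are above the threshold, so post-contact (flat) samples cannot
    flatten the estimate — and pooled with a median across touchdowns.
    """
    slopes = [(y[f - 2] - y[f - 1]) / dt for f in frames
              if f >= 2 and y[f - 2] > y[f - 1] >= threshold]
    return float(np.median(slopes)) if slopes else None


def detect_stance_onsets(time: np.ndarray, toe_y: np.ndarray,
                         params: EventParams = EventParams()) -> np.ndarray:
    """Times of stance onsets (first frame of each sustained contact run)."""
    time = np.asarray(time, float)
    toe_y = np.asarray(toe_y, float)
    if time.size < 2:
        raise ValueError("trajectory must span at least 2 frames")
    if time[-1] - time[0] < 0.5:
        raise ValueError("trajectory must span at least 0.5 s")
    if not np.all(np.isfinite(toe_y)):
        raise ValueError("toe trajectory contains non-finite values")
    contact = toe_y < params.height_threshold
    runs = _contact_runs(contact, params.min_contact_frames)
    frames = [a for a, _ in runs if a > 0]  # a == 0: no observed transition
    if not params.refine:
        return time[np.asarray(frames, dtype=int)] if frames else np.empty(0)
    # contact = the last airborne sample extrapolated to the belt surface at
    # the limb's common terminal descent speed; falls back to interpolating
    # the threshold crossing when the speed cannot be estimated
    dt = float(np.median(np.diff(time)))
    speed = _descent_speed(toe_y, frames, params.height_threshold, dt)
    onsets = []
    for f in frames:
        if speed and f > 0 and toe_y[f - 1] > toe_y[f]:
            t = float(np.clip(time[f - 1] + toe_y[f - 1] / speed,
                              time[f - 1], time[f] + dt))
        else:
            t = _crossing_time(time, toe_y, f, params.height_threshold)
        onsets.append(t)
    return np.asarray(onsets)


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def _refine_offset(time: np.ndarray, x: np.ndarray, m: int,
                   t_next_onset: float) -> float:
    """Liftoff as the intersection of the stance line with the caudal plateau.

    During stance x falls linearly at belt speed. The early-swing samples
    used to estimate the plateau level are corrected for the forward swing
    displacement, modelled as a minimum-jerk point-to-point profile (the
    standard smooth-limb-trajectory model) from the caudal extreme to the
    next touchdown.
    """
    if m < 12 or m + 9 >= x.size:
        return float(time[m])
    t_ref = time[m]
    dt = float(np.median(np.diff(time)))
    sel = np.arange(m - 10, m + 9)
    ts = time[sel] - t_ref  # (n,)
    xs = x[sel]
    x_td = float(np.interp(t_next_onset, time, x))
    tau_total = t_next_onset - t_ref
    if tau_total <= 2 * dt:
        return float(time[m])
    # grid over candidate kink times; per candidate the model
    #   x(t) = A - v * (t_k - t)_+ + (x_td - A) * minjerk((t - t_k)/tau)
    # is linear in (A, v) and solved in closed form
    tk = np.linspace(-1.3 * dt, 1.3 * dt, 27)  # (g,)
    w = ts[:, None] - tk[None, :]  # (n, g)
    mj = _minimum_jerk(np.maximum(w, 0.0) / (tau_total - tk)[None, :])
    c1 = 1.0 - mj
    c2 = np.minimum(w, 0.0)
    b = xs[:, None] - x_td * mj
    s11 = np.sum(c1 * c1, axis=0)
    s12 = np.sum(c1 * c2, axis=0)
    s22 = np.sum(c2 * c2, axis=0)
    r1 = np.sum(c1 * b, axis=0)
    r2 = np.sum(c2 * b, axis=0)
    det = s11 * s22 - s12 * s12
    det = np.where(np.abs(det) < 1e-30, np.nan, det)
    a_hat = (r1 * s22 - r2 * s12) / det
    # v_hat is the slope on (t - t_k)_- : a negative value means x falls at
    # belt speed toward the kink, as a stance line must
    v_hat = (s11 * r2 - s12 * r1) / det
    sse = np.sum((b - a_hat * c1 - v_hat * c2) ** 2, axis=0)
    sse = np.where(np.isfinite(sse) & (v_hat < 0), sse, np.inf)
    g = int(np.argmin(sse))
    if not np.isfinite(sse[g]):
        return float(time[m])
    t_star = tk[g]
    if 0 < g < tk.size - 1 and np.isfinite(sse[g - 1] + sse[g + 1]):
        denom = sse[g - 1] - 2 * sse[g] + sse[g + 1]
        if denom > 0:  # parabolic refinement of the SSE minimum
            t_star += 0.5 * (sse[g - 1] - sse[g + 1]) / denom * (tk[1] - tk[0])
    return float(t_ref + np.clip(t_star, -1.5 * dt, 1.5 * dt))


def detect_stance_offsets(time: np.ndarray, toe_x: np.ndarray,
                          onsets: np.ndarray,
                          params: EventParams = EventParams()) -> np.ndarray:
    """Offset per stance run: the most caudal toe x within [onset, next onset).

    Returns one offset per consecutive onset pair; a pair whose x minimum
    falls on the window edge (no caudal turning point) yields NaN and the
    cycle is excluded downstream.
    """
    time = np.asarray(time, float)
    toe_x = np.asarray(toe_x, float)
    onsets = np.asarray(onsets, float)
    if onsets.size == 0:
        raise ValueError("no stance onsets supplied")
    offsets = np.full(max(onsets.size - 1, 0), np.nan)
    for i in range(onsets.size - 1):
        a = int(np.searchsorted(time, onsets[i], side="left"))
        b = int(np.searchsorted(time, onsets[i + 1], side="left"))
        if b - a < 3:
            continue
        seg = toe_x[a:b]
        m = a + int(np.argmin(seg))
        if m == a or m == b - 1:
            continue  # monotone within the window: no turning point
        offsets[i] = (_refine_offset(time, toe_x, m, onsets[i + 1])
                      if params.refine else float(time[m]))
    return offsets


def build_cycles(onsets: np.ndarray, offsets: np.ndarray,
                 limb: str) -> list[GaitCycle]:
    """One GaitCycle per consecutive onset pair with a valid offset between.

    Cycles whose offset is missing (NaN) or falls outside the onset pair are
    dropped.
    """
    onsets = np.asarray(onsets, float)
    offsets = np.asarray(offsets, float)
    if offsets.size != max(onsets.size - 1, 0):
        raise ValueError("expected one (possibly NaN) offset per onset pair")
    cycles = []
    for i in range(onsets.size - 1):
        off = offsets[i]
        if not np.isfinite(off):
            continue
        if not onsets[i] < off < onsets[i + 1]:
            raise ValueError(
                f"{limb}: offset {off} not inside onsets "
                f"({onsets[i]}, {onsets[i + 1]})")
        cycles.append(GaitCycle(limb=limb, index=i, stance_onset=onsets[i],
                                stance_offset=off, next_onset=onsets[i + 1]))
    return cycles


def detect_cycles(time: np.ndarray, toe_xy: np.ndarray, limb: str,
                  params: EventParams = EventParams()) -> list[GaitCycle]:
    """Convenience: full onset/offset detection and cycle assembly."""
    onsets = detect_stance_onsets(time, toe_xy[:, 1], params)
    if onsets.size < 2:
        return []
    offsets = detect_stance_offsets(time, toe_xy[:, 0], onsets, params)
    return build_cycles(onsets, offsets, limb)
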