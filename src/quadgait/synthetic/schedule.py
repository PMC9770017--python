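"""Footfall schedules: periodic stance/swing timing for the four limbs.

A schedule is the temporal ground truth of a synthetic session: for each limb
role an ordered array of (stance onset, stance offset) event pairs. The
default walking parameters give the canonical support-period structure of a
slow quadrupedal walk: duty factor 0.65 on all limbs, hindlimbs half a cycle
apart, each forelimb a quarter cycle after its homolateral hindlimb — which
decomposes into eight alternating double/triple support periods per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io_core import LIMB_ROLES, MUSCLES

#: canonical limb phase offsets (fraction of cycle after the ipsilateral
#: hindlimb stance onset)
DEFAULT_PHASE_OFFSETS = {
    "ipsi_hind": 0.0,
    "contra_hind": 0.5,
    "homo_fore": 0.25,
    "diag_fore": 0.75,
}


@dataclass
class FootfallSchedule:
    """Per-limb stance intervals plus the generating parameters."""

    events: dict[str, np.ndarray]  # role -> (n_cycles, 2) [onset, offset], s
    cycle_period: float  # s
    duty_factor: dict[str, float]
    phase_offsets: dict[str, float]

    def __post_init__(self) -> None:
        for role, ev in self.events.items():
            ev = np.asarray(ev, dtype=float)
            if ev.ndim != 2 or ev.shape[1] != 2:
                raise ValueError(f"{role}: events must be (n, 2)")
            if not (np.all(ev[:, 0] < ev[:, 1])
                    and np.all(ev[:-1, 1] < ev[1:, 0])):
                raise ValueError(f"{role}: events must satisfy "
                                 "onset < offset < next onset")
            self.events[role] = ev

    def stance_intervals(self, role: str) -> np.ndarray:
        return self.events[role]

    def n_cycles(self, role: str = "ipsi_hind") -> int:
        return self.events[role].shape[0] - 1

    def span(self) -> tuple[float, float]:
        lo = min(ev[0, 0] for ev in self.events.values())
        hi = max(ev[-1, 1] for ev in self.events.values())
        return lo, hi

    def copy(self) -> "FootfallSchedule":
        return FootfallSchedule(
            events={r: ev.copy() for r, ev in self.events.items()},
            cycle_period=self.cycle_period,
            duty_factor=dict(self.duty_factor),
            phase_offsets=dict(self.phase_offsets),
        )


def build_footfall_schedule(
    cycle_period: float = 1.0,
    duty_factor: float | dict[str, float] = 0.65,
    phase_offsets: dict[str, float] | None = None,
    n_cycles: int = 10,
    t0: float = 0.0,
    timing_jitter_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FootfallSchedule:
    """Build a periodic four-limb schedule, optionally with per-event jitter.

    Jitter is applied independently per event around the periodic grid, so it
    does not accumulate over the session.
    """
    if cycle_period <= 0:
        raise ValueError("cycle_period must be positive")
    offsets = dict(DEFAULT_PHASE_OFFSETS if phase_offsets is None else phase_offsets)
    duty = ({r: duty_factor for r in LIMB_ROLES}
            if np.isscalar(duty_factor) else dict(duty_factor))
    for r in LIMB_ROLES:
        if not 0.0 < duty[r] < 1.0:
            raise ValueError(f"duty factor for {r} must be in (0, 1)")
        if not 0.0 <= offsets[r] < 1.0:
            raise ValueError(f"phase offset for {r} must be in [0, 1)")
    if timing_jitter_sigma < 0:
        raise ValueError("timing_jitter_sigma must be >= 0")
    if timing_jitter_sigma > 0 and rng is None:
        raise ValueError("jitter requires an rng")

    events: dict[str, np.ndarray] = {}
    k = np.arange(n_cycles + 1)
    for role in LIMB_ROLES:
        onsets = t0 + (k + offsets[role]) * cycle_period
        stance = duty[role] * cycle_period
        offs = onsets + stance
        if timing_jitter_sigma > 0:
            onsets = onsets + rng.normal(0.0, timing_jitter_sigma, onsets.shape)
            offs = offs + rng.normal(0.0, timing_jitter_sigma, offs.shape)
        events[role] = np.column_stack([onsets, offs])
    return FootfallSchedule(events=events, cycle_period=cycle_period,
                            duty_factor=duty, phase_offsets=offsets)


# ---------------------------------------------------------------------------
# Animal parameters
# ---------------------------------------------------------------------------

#: which animals carry which muscle (both sides); patterned on a typical
#: chronic-implant cohort where some electrodes fail per animal:
#: SRT and TRI in 7/7, ST/LG/SOL/BB in 6/7, BFP/BFA/VL/ECU in 5/7.
MUSCLE_AVAILABILITY: dict[str, frozenset[int]] = {
    "SRT": frozenset(range(7)),
    "TRI": frozenset(range(7)),
    "ST": frozenset({0, 1, 2, 3, 5, 6}),
    "LG": frozenset({0, 1, 3, 4, 5, 6}),
    "SOL": frozenset({0, 1, 2, 3, 5, 6}),
    "BB": frozenset({1, 2, 3, 4, 5, 6}),
    "BFP": frozenset({0, 1, 3, 5, 6}),
    "BFA": frozenset({0, 1, 3, 5, 6}),
    "VL": frozenset({0, 1, 3, 5, 6}),
    "ECU": frozenset({0, 2, 3, 4, 6}),
}


@dataclass
class AnimalParams:
    """Per-animal baseline gait, morphology and noise parameters."""

    name: str = "cat01"
    index: int = 0
    cycle_period: float = 1.1  # s
    duty_factor: float = 0.65
    #: diagonal forelimb lands slightly early relative to the symmetric 0.75,
    #: so the contra–homo diagonal support is brief, as in walking cats
    phase_offsets: dict[str, float] = field(default_factory=lambda: {
        "ipsi_hind": 0.0, "contra_hind": 0.5, "homo_fore": 0.25,
        "diag_fore": 0.71})
    belt_speed: float = 0.4  # m/s
    # hindlimb segment lengths, m
    thigh: float = 0.11
    shank: float = 0.12
    foot: float = 0.06
    # forelimb segment lengths, m
    arm: float = 0.10
    forearm: float = 0.10
    paw: float = 0.05
    hip_height: float = 0.26
    shoulder_height: float = 0.28
    swing_apex: float = 0.03  # m, toe clearance at mid-swing
    #: EMG baseline burst amplitude per muscle, arbitrary volts
    emg_amplitude: dict[str, float] = field(
        default_factory=lambda: {m: 1e-4 for m in MUSCLES})
    muscles: tuple[str, ...] = MUSCLES
    # noise scales
    marker_jitter_sigma: float = 0.0005  # m
    timing_jitter_sigma: float = 0.002  # s
    emg_snr: float = 20.0  # burst amplitude / baseline noise amplitude

    def __post_init__(self) -> None:
        for nm in ("thigh", "shank", "foot", "arm", "forearm", "paw",
                   "hip_height", "shoulder_height", "swing_apex"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.marker_jitter_sigma < 0 or self.timing_jitter_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must be in (0, 1)")


def sample_animals(n_animals: int, belt_speed: float,
                   rng: np.random.Generator,
                   between_animal_sigma: float = 0.05,
                   noise: bool = True) -> list[AnimalParams]:
    """Draw a cohort with multiplicative log-normal between-animal effects.

    With ``noise=False`` every animal is identical to the baseline and has
    zero within-session noise (the zero-noise study condition used by the
    exactness tests).
    """
    animals = []
    for i in range(n_animals):
        muscles = tuple(m for m in MUSCLES if i in MUSCLE_AVAILABILITY[m])
        if noise:
            period = 1.1 * rng.lognormal(0.0, between_animal_sigma)
            speed = belt_speed + rng.uniform(-0.05, 0.05)
            amps = {m: 1e-4 * rng.lognormal(0.0, 0.3) for m in MUSCLES}
            a = AnimalParams(name=f"cat{i + 1:02d}", index=i,
                             cycle_period=period, belt_speed=speed,
                             emg_amplitude=amps, muscles=muscles)
        else:
            a = AnimalParams(name=f"cat{i + 1:02d}", index=i,
                             belt_speed=belt_speed, muscles=muscles,
                             marker_jitter_sigma=0.0,
                             timing_jitter_sigma=0.0,
                             emg_snr=float("inf"))
        animals.append(a)
    return animals
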