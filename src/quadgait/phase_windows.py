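"""Stimulus phase classification and control/stimulated/post triad extraction.

Each stimulus is located within the ipsilateral hindlimb cycle that contains
its onset, expressed as a fraction of that cycle's own stance or swing
sub-phase, and classified into one of the four targeted phases (or excluded).
For every limb the stimulated cycle is the limb's own cycle containing the
stimulus onset; the control and post cycles are its immediate neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gait_events import GaitCycle
from .io_core import LIMB_ROLES, StimulusEvent

EXCLUDED = "excluded"

CYCLE_POSITIONS = ("control", "stim", "post")


@dataclass(frozen=True)
class PhaseWindows:
    """Classification windows on the normalized sub-phase fractions.

    Mid-phase windows are centred 40%-of-sub-phase bands; transition windows
    span the last 10% of the outgoing sub-phase and the first 10% of the
    incoming one. Windows must not overlap.
    """

    mid_stance: tuple[float, float] = (0.3, 0.7)
    mid_swing: tuple[float, float] = (0.3, 0.7)
    transition_before: float = 0.9  # outgoing sub-phase fraction above this
    transition_after: float = 0.1  # incoming sub-phase fraction below this

    def __post_init__(self) -> None:
        for lo, hi in (self.mid_stance, self.mid_swing):
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError("mid-phase windows must satisfy 0 <= lo < hi <= 1")
        if not (self.transition_after <= self.mid_stance[0]
                and self.mid_stance[1] <= self.transition_before
                and self.transition_after <= self.mid_swing[0]
                and self.mid_swing[1] <= self.transition_before):
            raise ValueError("phase windows overlap")


def normalized_phase(onset: float, cycle: GaitCycle
                     ) -> tuple[float, float | None, float | None]:
    """(cycle phase, stance fraction, swing fraction) of a time in a cycle.

    The sub-phase fraction not containing the time is None.
    """
    if not cycle.contains(onset):
        raise ValueError(f"time {onset} outside cycle "
                         f"[{cycle.stance_onset}, {cycle.next_onset})")
    phase = (onset - cycle.stance_onset) / cycle.cycle_duration
    if onset < cycle.stance_offset:
        return phase, (onset - cycle.stance_onset) / cycle.stance_duration, None
    return phase, None, (onset - cycle.stance_offset) / cycle.swing_duration


def classify_phase(stance_fraction: float | None, swing_fraction: float | None,
                   windows: PhaseWindows = PhaseWindows()) -> str:
    """Phase label for a stimulus, or ``excluded``."""
    if (stance_fraction is None) == (swing_fraction is None):
        raise ValueError("exactly one of stance/swing fraction must be given")
    if stance_fraction is not None:
        f = stance_fraction
        if windows.mid_stance[0] <= f <= windows.mid_stance[1]:
            return "mid_stance"
        if f > windows.transition_before:
            return "stance_to_swing"
        if f < windows.transition_after:
            return "swing_to_stance"  # just after the preceding touchdown
        return EXCLUDED
    f = swing_fraction
    if windows.mid_swing[0] <= f <= windows.mid_swing[1]:
        return "mid_swing"
    if f > windows.transition_before:
        return "swing_to_stance"
    if f < windows.transition_after:
        return "stance_to_swing"
    return EXCLUDED


@dataclass
class CycleTriad:
    """Control/stimulated/post cycles of all four limbs around one stimulus."""

    stimulus: StimulusEvent
    stim_index: int
    phase: str
    cycles: dict[str, tuple[GaitCycle, GaitCycle, GaitCycle]] = field(
        default_factory=dict)
    valid: bool = True
    reason: str = ""

    def cycle(self, role: str, position: str) -> GaitCycle:
        return self.cycles[role][CYCLE_POSITIONS.index(position)]


def _find_containing(cycles: list[GaitCycle], t: float) -> int | None:
    onsets = np.array([c.stance_onset for c in cycles])
    i = int(np.searchsorted(onsets, t, side="right")) - 1
    if 0 <= i < len(cycles) and cycles[i].contains(t):
        return i
    return None


def extract_triads(stimuli: list[StimulusEvent],
                   cycles_by_limb: dict[str, list[GaitCycle]],
                   windows: PhaseWindows = PhaseWindows()) -> list[CycleTriad]:
    """Assemble one triad per stimulus, marking invalid ones with a reason.

    A triad is invalid if the stimulus phase is excluded, if any limb lacks
    three consecutive complete cycles around the stimulus, or if another
    stimulus falls within the ipsilateral control-to-post span.
    """
    for role in LIMB_ROLES:
        if role not in cycles_by_limb:
            raise ValueError(f"missing cycles for limb {role}")
    ipsi = cycles_by_limb["ipsi_hind"]
    onsets_all = np.array([s.onset for s in stimuli])
    triads: list[CycleTriad] = []
    for si, stim in enumerate(stimuli):
        i = _find_containing(ipsi, stim.onset)
        if i is None:
            triads.append(CycleTriad(stim, si, EXCLUDED, valid=False,
                                     reason="no ipsilateral cycle contains "
                                            "the stimulus"))
            continue
        _, st_f, sw_f = normalized_phase(stim.onset, ipsi[i])
        phase = classify_phase(st_f, sw_f, windows)
        triad = CycleTriad(stim, si, phase)
        if phase == EXCLUDED:
            triad.valid = False
            triad.reason = "stimulus outside the defined phase windows"
        for role in LIMB_ROLES:
            cyc = cycles_by_limb[role]
            j = _find_containing(cyc, stim.onset)
            if j is None or j == 0 or j + 1 >= len(cyc):
                triad.valid = False
                triad.reason = triad.reason or f"incomplete cycles for {role}"
                break
            ctrl, stc, post = cyc[j - 1], cyc[j], cyc[j + 1]
            # the three cycles must be consecutive in time, not merely in
            # list order (a dropped cycle leaves a gap)
            if (abs(ctrl.next_onset - stc.stance_onset) > 1e-9
                    or abs(stc.next_onset - post.stance_onset) > 1e-9):
                triad.valid = False
                triad.reason = triad.reason or f"non-consecutive cycles for {role}"
                break
            triad.cycles[role] = (ctrl, stc, post)
        if triad.valid:
            span_lo = triad.cycles["ipsi_hind"][0].stance_onset
            span_hi = triad.cycles["ipsi_hind"][2].next_onset
            others = onsets_all[(onsets_all >= span_lo) & (onsets_all < span_hi)]
            if others.size > 1:
                triad.valid = False
                triad.reason = "another stimulus within the triad span"
        triads.append(triad)
    return triads
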