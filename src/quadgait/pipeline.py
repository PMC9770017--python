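"""End-to-end analysis: markers + EMG + stimuli -> triad metrics tables.

The long-format metrics table has one row per (stimulus triad, cycle
position, variable, limb) and feeds directly into the statistics module.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emg_analysis import (BurstParams, bandpass_filter, burst_metrics,
                           detect_bursts, envelope)
from .gait_events import EventParams, GaitCycle, detect_cycles
from .io_core import (EMGRecording, LIMB_ROLES, MarkerTrajectories,
                      StimulusEvent, limb_roles_for, toe_marker)
from .phase_windows import (CYCLE_POSITIONS, CycleTriad, PhaseWindows,
                            extract_triads)
from .spatiotemporal import (angle_summary, category_durations, joint_angle,
                             max_height, step_length, stride_length,
                             support_periods)
from .synthetic.emg import muscle_role

logger = logging.getLogger("quadgait")

_PARTNER = {"ipsi_hind": "contra_hind", "contra_hind": "ipsi_hind",
            "homo_fore": "diag_fore", "diag_fore": "homo_fore"}

#: landmarks whose cycle-maximum height is reported, per girdle
HEIGHT_LANDMARKS = {
    "hind": (("trochanter", "height_hip"), ("knee", "height_knee"),
             ("hind_toe", "height_toe")),
    "fore": (("humerus", "height_shoulder"), ("elbow", "height_elbow"),
             ("fore_toe", "height_toe")),
}

#: hindlimb joint definitions: joint -> (proximal, vertex, distal markers)
JOINT_MARKERS = {
    "hip": ("iliac_crest", "trochanter", "knee"),
    "knee": ("trochanter", "knee", "malleolus"),
    "ankle": ("knee", "malleolus", "mtp"),
}


@dataclass
class AnimalAnalysis:
    animal: str
    stim_side: str
    cycles: dict[str, list[GaitCycle]]
    triads: list[CycleTriad]
    metrics: pd.DataFrame
    n_valid: int = 0
    notes: dict = field(default_factory=dict)


def _stance_intervals(cycles: list[GaitCycle]) -> np.ndarray:
    return np.array([[c.stance_onset, c.stance_offset] for c in cycles])


def _triad_cycle_pos(cycles: list[GaitCycle], cyc: GaitCycle) -> int:
    onsets = [c.stance_onset for c in cycles]
    i = bisect.bisect_right(onsets, cyc.stance_onset) - 1
    return i


def analyze_animal(markers: MarkerTrajectories,
                   stimuli: list[StimulusEvent],
                   emg: EMGRecording | None = None,
                   belt_speed: float | None = None,
                   event_params: EventParams = EventParams(),
                   windows: PhaseWindows = PhaseWindows(),
                   burst_params: BurstParams = BurstParams()
                   ) -> AnimalAnalysis:
    """Detect cycles, extract triads and compute all per-cycle metrics."""
    if belt_speed is None:
        belt_speed = markers.belt_speed
    if not np.isfinite(belt_speed) or belt_speed <= 0:
        raise ValueError("a positive belt speed is required")
    stim_side = stimuli[0].limb if stimuli else "right"
    roles = limb_roles_for(stim_side)
    t = markers.time

    cycles: dict[str, list[GaitCycle]] = {}
    toe_xy: dict[str, np.ndarray] = {}
    for role, (side, girdle) in roles.items():
        xy = markers.xy(*toe_marker(side, girdle))
        toe_xy[role] = xy
        cycles[role] = detect_cycles(t, xy, role, event_params)
    triads = extract_triads(stimuli, cycles, windows)
    stance_iv = {r: _stance_intervals(cycles[r]) for r in LIMB_ROLES}

    # full-session ipsilateral hindlimb joint-angle series
    ipsi_side = roles["ipsi_hind"][0]
    angle_series = {
        joint: joint_angle(markers.xy(ipsi_side, a), markers.xy(ipsi_side, b),
                           markers.xy(ipsi_side, c))
        for joint, (a, b, c) in JOINT_MARKERS.items()}

    emg_data = _prepare_emg(emg, cycles, stim_side, burst_params) if emg else {}

    rows: list[dict] = []
    n_valid = 0
    for triad in triads:
        if not triad.valid:
            continue
        n_valid += 1
        base = {"animal": markers.animal, "stim_index": triad.stim_index,
                "phase": triad.phase}
        for pos_i, pos in enumerate(CYCLE_POSITIONS):
            ipsi_cyc = triad.cycles["ipsi_hind"][pos_i]
            add = rows.append

            for role in LIMB_ROLES:
                cyc = triad.cycles[role][pos_i]
                add({**base, "position": pos, "limb": role,
                     "variable": "cycle_duration", "value": cyc.cycle_duration})
                add({**base, "position": pos, "limb": role,
                     "variable": "stance_duration", "value": cyc.stance_duration})
                add({**base, "position": pos, "limb": role,
                     "variable": "swing_duration", "value": cyc.swing_duration})

                # step length at the touchdown closing this cycle
                partner = _PARTNER[role]
                try:
                    sl = step_length(t, toe_xy[role][:, 0],
                                     toe_xy[partner][:, 0], cyc.next_onset)
                    add({**base, "position": pos, "limb": role,
                         "variable": "step_length", "value": sl})
                except ValueError:
                    pass
                add({**base, "position": pos, "limb": role,
                     "variable": "stride_length",
                     "value": stride_length(cyc, t, toe_xy[role][:, 0],
                                            belt_speed)})
                girdle = roles[role][1]
                side = roles[role][0]
                for marker, varname in HEIGHT_LANDMARKS[girdle]:
                    h = max_height(t, markers.xy(side, marker)[:, 1], cyc)
                    add({**base, "position": pos, "limb": role,
                         "variable": varname, "value": h})

            # support periods within the ipsilateral cycle window
            periods = support_periods(
                stance_iv, (ipsi_cyc.stance_onset, ipsi_cyc.next_onset))
            for cat, dur in category_durations(periods).items():
                add({**base, "position": pos, "limb": "",
                     "variable": f"support_{cat}", "value": dur})

            # ipsilateral hindlimb joint angles
            for joint, series in angle_series.items():
                summ = angle_summary(t, series, ipsi_cyc, joint)
                if not summ.valid:
                    continue
                for stat, val in (("contact", summ.at_contact),
                                  ("liftoff", summ.at_liftoff),
                                  ("max", summ.max), ("min", summ.min),
                                  ("excursion", summ.excursion)):
                    add({**base, "position": pos, "limb": "ipsi_hind",
                         "variable": f"angle_{joint}_{stat}", "value": val})

        rows.extend(_emg_rows(triad, emg_data, cycles, base))

    metrics = pd.DataFrame(rows, columns=["animal", "stim_index", "phase",
                                          "position", "limb", "variable",
                                          "value"])
    return AnimalAnalysis(animal=markers.animal, stim_side=stim_side,
                          cycles=cycles, triads=triads, metrics=metrics,
                          n_valid=n_valid)


def _prepare_emg(emg: EMGRecording, cycles: dict[str, list[GaitCycle]],
                 stim_side: str, burst_params: BurstParams) -> dict:
    """Filter each channel and detect one burst per limb cycle."""
    out = {}
    for (side, muscle), raw in emg.channels.items():
        role = muscle_role(side, muscle, stim_side)
        filt = bandpass_filter(raw, emg.rate)
        rect = np.abs(filt)
        env = envelope(filt, emg.rate)
        wins = [(c.stance_onset, c.next_onset) for c in cycles[role]]
        bursts = detect_bursts(emg.time, env, emg.rate, wins, burst_params)
        out[(side, muscle)] = {"role": role, "rect": rect, "time": emg.time,
                               "bursts": bursts}
    return out


def _emg_rows(triad: CycleTriad, emg_data: dict,
              cycles: dict[str, list[GaitCycle]], base: dict) -> list[dict]:
    rows: list[dict] = []
    for (side, muscle), ch in emg_data.items():
        role = ch["role"]
        pos_bursts = []
        for pos_i in range(3):
            cyc = triad.cycles[role][pos_i]
            li = _triad_cycle_pos(cycles[role], cyc)
            b = ch["bursts"][li] if 0 <= li < len(ch["bursts"]) else None
            pos_bursts.append(b)
        if pos_bursts[0] is None:
            continue
        ctrl = burst_metrics(ch["time"], ch["rect"], pos_bursts[0],
                             muscle=muscle, side=side)
        if ctrl.mean_amplitude <= 0:
            continue
        for pos, b in zip(CYCLE_POSITIONS, pos_bursts):
            if b is None:
                continue
            m = burst_metrics(ch["time"], ch["rect"], b, muscle=muscle,
                              side=side, control_mean=ctrl.mean_amplitude)
            rows.append({**base, "position": pos, "limb": role,
                         "variable": f"emg_amp_{muscle}",
                         "value": m.normalized_amplitude})
            rows.append({**base, "position": pos, "limb": role,
                         "variable": f"emg_dur_{muscle}",
                         "value": m.duration})
    return rows


#: the headline group effects of the study: (name, variable, phase, limb,
#: how the percent is computed: "pct" = percent change vs control of the
#: per-animal means; "norm" = group mean of control-normalized amplitude
#: minus 100 (the convention used for EMG amplitudes)
HEADLINE_EFFECTS = (
    ("ipsi_swing_mid_swing", "swing_duration", "mid_swing", "ipsi_hind", "pct"),
    ("ipsi_cycle_mid_swing", "cycle_duration", "mid_swing", "ipsi_hind", "pct"),
    ("ipsi_swing_stance_to_swing", "swing_duration", "stance_to_swing",
     "ipsi_hind", "pct"),
    ("contra_swing_mid_stance", "swing_duration", "mid_stance", "contra_hind",
     "pct"),
    ("homo_swing_swing_to_stance", "swing_duration", "swing_to_stance",
     "homo_fore", "pct"),
    ("contra_homo_support_mid_swing", "support_contra_homo", "mid_swing", "",
     "pct"),
    ("contra_homo_support_stance_to_swing", "support_contra_homo",
     "stance_to_swing", "", "pct"),
    ("ipsi_toe_height_stance_to_swing", "height_toe", "stance_to_swing",
     "ipsi_hind", "pct"),
    ("contra_step_length_mid_swing", "step_length", "mid_swing",
     "contra_hind", "pct"),
    ("ipsi_st_amplitude_stance_to_swing", "emg_amp_ST", "stance_to_swing",
     "ipsi_hind", "norm"),
)


def recovered_percent_changes(metrics: pd.DataFrame
                              ) -> dict[str, tuple[float, int]]:
    """Group percent change (and animal count) for each headline effect."""
    from .stats_report import build_table

    out: dict[str, tuple[float, int]] = {}
    for name, variable, phase, limb, kind in HEADLINE_EFFECTS:
        table = build_table(metrics, variable, phase, limb or None)
        if table is None:
            continue
        n = int(table.matrix.dropna().shape[0])
        if kind == "norm":
            out[name] = (table.group_mean["stim"] - 100.0, n)
        else:
            out[name] = (table.pct_change["stim"][0], n)
    return out


@dataclass
class SessionAnalysis:
    animals: list[AnimalAnalysis]
    metrics: pd.DataFrame

    def n_valid_triads(self) -> int:
        return sum(a.n_valid for a in self.animals)


def analyze_session(recordings: list[tuple[MarkerTrajectories,
                                           list[StimulusEvent],
                                           EMGRecording | None]],
                    belt_speeds: list[float] | None = None,
                    **kwargs) -> SessionAnalysis:
    """Analyze every animal and concatenate the metrics tables."""
    analyses = []
    for i, (markers, stimuli, emg) in enumerate(recordings):
        bs = belt_speeds[i] if belt_speeds else None
        analyses.append(analyze_animal(markers, stimuli, emg,
                                       belt_speed=bs, **kwargs))
    metrics = pd.concat([a.metrics for a in analyses], ignore_index=True)
    return SessionAnalysis(animals=analyses, metrics=metrics)
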