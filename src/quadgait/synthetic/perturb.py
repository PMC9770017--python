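"""Stimulus planning and phase-specific perturbation of synthetic sessions.

A session plan is the complete ground truth of one animal's recording: the
four-limb event timeline, per-swing toe apex heights, per-touchdown landing
positions, joint-flexion modifiers and EMG gain annotations, plus the planted
stimuli. Perturbation works by *regenerating the affected cycle from modified
schedule parameters* — durations, touchdown times and landing positions are
recomputed from the target effect ratios, never by warping already-generated
signals — so every injected effect is exactly recoverable in the noise-free
limit.

Two effects are emergent rather than directly assignable and are therefore
solved from the schedule geometry at injection time:

* the contra–homo diagonal support duration (the interval between the
  ipsilateral liftoff and the diagonal forelimb touchdown while the
  homolateral forelimb is still in stance) is set by delaying the diagonal
  touchdown to ``ipsi liftoff + gain x baseline gap``;
* a step-length ratio is achieved by shifting the landing position of the
  touchdown that closes the stimulated cycle, relative to the partner limb's
  extrapolated position at that instant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io_core import (LIMB_ROLES, PerturbationProfile, SessionConfig,
                       StimulusEvent)
from .schedule import AnimalParams, build_footfall_schedule

#: lead-in / lead-out cycles outside the recorded span
_PAD_CYCLES = 3

#: stimulus placement windows, as a fraction of the containing sub-phase;
#: each sits inside the corresponding classification window with margin
STIM_PLACEMENT = {
    "mid_stance": ("stance", 0.35, 0.65),
    "stance_to_swing": ("swing", 0.01, 0.08),
    "mid_swing": ("swing", 0.35, 0.65),
    "swing_to_stance": ("swing", 0.92, 0.98),
}

#: forelimb girdle sits anterior to the hindlimb girdle by this much (m)
FORE_GIRDLE_OFFSET = 0.25

_PARTNER = {"ipsi_hind": "contra_hind", "contra_hind": "ipsi_hind",
            "homo_fore": "diag_fore", "diag_fore": "homo_fore"}


@dataclass
class SessionPlan:
    """Ground-truth description of one synthetic animal recording."""

    animal: AnimalParams
    stim_side: str
    duration: float  # s of recorded data, starting at t = 0
    events: dict[str, np.ndarray]  # role -> (n, 2) stance [onset, offset]
    apex: dict[str, np.ndarray]  # role -> (n,) apex of the swing after stance i
    td_x: dict[str, np.ndarray]  # role -> (n,) toe landing x at onset i
    #: ipsi cycle index -> joint name -> multiplier on the minimum joint angle
    flex_mult: dict[int, dict[str, float]] = field(default_factory=dict)
    #: (role, muscle) -> cycle index -> (amplitude gain, duration gain)
    emg_gain: dict[tuple[str, str], dict[int, tuple[float, float]]] = field(
        default_factory=dict)
    stimuli: list[StimulusEvent] = field(default_factory=list)
    truth: list[dict] = field(default_factory=list)

    def cycle_containing(self, role: str, t: float) -> int:
        """Index i with onset_i <= t < onset_{i+1} for the given limb."""
        onsets = self.events[role][:, 0]
        i = int(np.searchsorted(onsets, t, side="right")) - 1
        if i < 0 or i >= onsets.size - 1:
            raise ValueError(f"time {t} outside the {role} schedule")
        return i


def make_baseline_plan(animal: AnimalParams, config: SessionConfig,
                       rng: np.random.Generator,
                       noise: bool = True) -> SessionPlan:
    """Unperturbed periodic plan covering the configured number of cycles."""
    T = animal.cycle_period
    n = config.cycles_per_animal + 2 * _PAD_CYCLES
    sched = build_footfall_schedule(
        cycle_period=T, duty_factor=animal.duty_factor,
        phase_offsets=animal.phase_offsets, n_cycles=n - 1,
        t0=-_PAD_CYCLES * T,
        timing_jitter_sigma=animal.timing_jitter_sigma if noise else 0.0,
        rng=rng)
    events = sched.events
    v = animal.belt_speed
    apex, td_x = {}, {}
    for role in LIMB_ROLES:
        m = events[role].shape[0]
        apex[role] = np.full(m, animal.swing_apex)
        base = v * animal.duty_factor * T / 2.0
        if role.endswith("fore"):
            base += FORE_GIRDLE_OFFSET
        td_x[role] = np.full(m, base)
    return SessionPlan(animal=animal, stim_side="right",
                       duration=config.cycles_per_animal * T,
                       events=events, apex=apex, td_x=td_x)


def _shuffled_gaps(n_stimuli: int, lo: int, hi: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random inter-stimulus spacings drawn evenly from [lo, hi]."""
    choices = np.arange(lo, hi + 1)
    gaps = np.tile(choices, int(np.ceil(n_stimuli / choices.size)))[:n_stimuli]
    rng.shuffle(gaps)
    return gaps


def plan_stimulus_cycles(config: SessionConfig, rng: np.random.Generator
                         ) -> list[tuple[int, str]]:
    """(ipsi cycle index, phase) for each planted stimulus of one animal.

    Raises if the requested stimuli do not fit into the session at the
    configured spacing.
    """
    phases = [p for p in config.phase_targets
              for _ in range(config.stimuli_per_phase)]
    phases = list(rng.permutation(phases))
    lo, hi = config.stim_every_cycles
    gaps = _shuffled_gaps(len(phases), lo, hi, rng)
    first = _PAD_CYCLES + 2
    cycles = first + np.concatenate([[0], np.cumsum(gaps[:-1])])
    last_allowed = _PAD_CYCLES + config.cycles_per_animal - 4
    if cycles[-1] > last_allowed:
        raise ValueError(
            f"{len(phases)} stimuli at {lo}-{hi} cycle spacing do not fit in "
            f"{config.cycles_per_animal} cycles")
    return list(zip(cycles.tolist(), phases))


def _jit(plan: SessionPlan, rng: np.random.Generator) -> float:
    s = plan.animal.timing_jitter_sigma
    return float(rng.normal(0.0, s)) if s > 0 else 0.0


def _set_limb_cycle(plan: SessionPlan, role: str, j: int,
                    stance: float, cycle: float,
                    rng: np.random.Generator) -> None:
    """Regenerate cycle j of one limb with the given durations.

    The following (post) cycle keeps its nominal duration; the cycle after
    that absorbs the accumulated shift and returns to the periodic grid.
    """
    ev = plan.events[role]
    on = ev[j, 0]
    ev[j, 1] = on + stance + _jit(plan, rng)
    new_next = on + cycle + _jit(plan, rng)
    shift = new_next - ev[j + 1, 0]
    ev[j + 1, 0] = new_next
    ev[j + 1, 1] += shift
    ev[j + 2, 0] += shift
    if not (ev[j, 0] < ev[j, 1] < ev[j + 1, 0]
            and ev[j + 2, 0] < ev[j + 2, 1]):
        raise ValueError(f"perturbed {role} cycle {j} violates event ordering")


def _limb_durations(prof: PerturbationProfile, role: str, T: float,
                    d: float, *, keep_stance_if_swing_only: bool
                    ) -> tuple[float, float] | None:
    """(stance, cycle) durations implied by the profile, or None if identity."""
    sm = prof.swing_multiplier.get(role)
    cm = prof.cycle_multiplier.get(role)
    stm = prof.stance_multiplier.get(role)
    if sm is None and cm is None and stm is None:
        return None
    swing0 = (1.0 - d) * T
    if cm is not None and sm is not None:
        cycle = cm * T
        stance = cycle - sm * swing0
    elif cm is not None and stm is not None:
        cycle = cm * T
        stance = stm * d * T
    elif sm is not None:
        if keep_stance_if_swing_only:
            stance = d * T  # swing prolongs the cycle (causal response)
            cycle = stance + sm * swing0
        else:
            cycle = T  # cycle preserved; stance yields to the swing change
            stance = cycle - sm * swing0
    elif stm is not None:
        stance = stm * d * T
        cycle = cm * T if cm is not None else T
    else:  # cm alone
        cycle = cm * T
        stance = cycle - swing0
    if not 0 < stance < cycle:
        raise ValueError(f"profile implies invalid durations for {role}")
    return stance, cycle


def inject_stimuli(plan: SessionPlan, profiles: dict[str, PerturbationProfile],
                   config: SessionConfig, rng: np.random.Generator
                   ) -> list[StimulusEvent]:
    """Plant stimuli and regenerate the affected cycles per phase profile.

    Modifies ``plan`` in place; returns the stimulus list (also stored on the
    plan, along with a ground-truth record per stimulus).
    """
    animal = plan.animal
    T, d, v = animal.cycle_period, animal.duty_factor, animal.belt_speed
    phi = animal.phase_offsets
    ipsi_ev = plan.events["ipsi_hind"]

    for k, phase in plan_stimulus_cycles(config, rng):
        prof = profiles.get(phase, PerturbationProfile.identity())
        record: dict = {"phase": phase, "ipsi_cycle": int(k), "effects": {}}

        # --- ipsilateral hindlimb cycle ------------------------------------
        dur = _limb_durations(prof, "ipsi_hind", T, d,
                              keep_stance_if_swing_only=True)
        if dur is not None:
            _set_limb_cycle(plan, "ipsi_hind", k, dur[0], dur[1], rng)
            record["effects"]["ipsi_stance"] = dur[0]
            record["effects"]["ipsi_cycle_dur"] = dur[1]

        # --- stimulus time inside the (possibly regenerated) ipsi cycle ----
        on, off = ipsi_ev[k]
        nxt = ipsi_ev[k + 1, 0]
        sub, lo, hi = STIM_PLACEMENT[phase]
        u = rng.uniform(lo, hi)
        t_s = on + (off - on) * u if sub == "stance" else off + (nxt - off) * u
        stim = StimulusEvent(onset=float(t_s), limb=plan.stim_side)
        plan.stimuli.append(stim)
        record["t_onset"] = float(t_s)

        # --- other limbs: duration changes in their cycle containing t_s ---
        for role in ("contra_hind", "homo_fore", "diag_fore"):
            dur = _limb_durations(prof, role, T, d,
                                  keep_stance_if_swing_only=False)
            if dur is not None:
                j = plan.cycle_containing(role, t_s)
                _set_limb_cycle(plan, role, j, dur[0], dur[1], rng)
                record["effects"][f"{role}_stance"] = dur[0]
                record["effects"][f"{role}_cycle_dur"] = dur[1]

        # --- contra–homo diagonal support: delay the diagonal touchdown ----
        if prof.support_gain_contra_homo is not None:
            gap0 = (phi["diag_fore"] - d) * T
            if gap0 <= 0:
                raise ValueError("support gain requires a positive baseline "
                                 "contra-homo gap (diag offset > duty)")
            target = prof.support_gain_contra_homo * gap0
            ipsi_off = ipsi_ev[k, 1]
            dg = plan.events["diag_fore"]
            m = int(np.searchsorted(dg[:, 0], ipsi_off))
            new_on = ipsi_off + target + _jit(plan, rng)
            if not dg[m - 1, 1] < new_on < dg[m, 1]:
                raise ValueError("diagonal touchdown delay violates ordering")
            dg[m, 0] = new_on  # stance shortened; next cycle back on grid
            record["effects"]["contra_homo_support"] = float(target)

        # --- step-length targets: shift the closing touchdown --------------
        for role, ratio in prof.step_length_ratio.items():
            j = plan.cycle_containing(role, t_s)
            partner = _PARTNER[role]
            t_td = plan.events[role][j + 1, 0]
            ons_p = plan.events[partner][:, 0]
            q = int(np.searchsorted(ons_p, t_td, side="right")) - 1
            x_p = plan.td_x[partner][q] - v * (t_td - ons_p[q])
            lag = (phi[role] - phi[partner]) % 1.0
            nominal = v * lag * T
            plan.td_x[role][j + 1] = x_p + ratio * nominal
            record["effects"][f"{role}_step_ratio"] = ratio

        # --- toe height, joint flexion, EMG gains ---------------------------
        if prof.toe_height_gain != 1.0:
            plan.apex["ipsi_hind"][k] *= prof.toe_height_gain
            record["effects"]["toe_height_gain"] = prof.toe_height_gain
        if prof.min_angle_multiplier:
            plan.flex_mult[k] = dict(prof.min_angle_multiplier)
        for key, amp in prof.emg_amplitude_gain.items():
            role, _, muscle = key.partition("/")
            j = plan.cycle_containing(role, t_s)
            plan.emg_gain.setdefault((role, muscle), {})
            prev = plan.emg_gain[(role, muscle)].get(j, (1.0, 1.0))
            plan.emg_gain[(role, muscle)][j] = (amp, prev[1])
        for key, gdur in prof.emg_duration_gain.items():
            role, _, muscle = key.partition("/")
            j = plan.cycle_containing(role, t_s)
            plan.emg_gain.setdefault((role, muscle), {})
            prev = plan.emg_gain[(role, muscle)].get(j, (1.0, 1.0))
            plan.emg_gain[(role, muscle)][j] = (prev[0], gdur)

        plan.truth.append(record)
    return plan.stimuli
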