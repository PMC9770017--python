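"""Whole-session orchestration of the synthetic data generator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from ..io_core import (EMGRecording, MarkerTrajectories, PerturbationProfile,
                       SessionConfig, StimulusEvent, profile_from_dict,
                       write_emg, write_marker_csv, write_stimuli)
from .emg import synthesize_emg
from .kinematics import synthesize_markers
from .perturb import SessionPlan, inject_stimuli, make_baseline_plan
from .schedule import AnimalParams, sample_animals


def load_paper_effects() -> dict[str, PerturbationProfile]:
    """The shipped phase->profile map with the published effect sizes."""
    text = (resources.files("quadgait.synthetic") / "paper_effects.yaml").read_text()
    raw = yaml.safe_load(text)
    return {phase: profile_from_dict(d) for phase, d in raw.items()}


@dataclass
class AnimalRecording:
    """One animal's complete synthetic recording plus its ground truth."""

    params: AnimalParams
    plan: SessionPlan
    markers: MarkerTrajectories
    emg: EMGRecording | None
    stimuli: list[StimulusEvent]

    @property
    def truth(self) -> list[dict]:
        return self.plan.truth


@dataclass
class SyntheticSession:
    config: SessionConfig
    profiles: dict[str, PerturbationProfile]
    animals: list[AnimalRecording] = field(default_factory=list)


def generate_session(config: SessionConfig,
                     profiles: dict[str, PerturbationProfile] | None = None,
                     noise: bool = True,
                     with_emg: bool = True,
                     emg_muscles: tuple[str, ...] | None = None
                     ) -> SyntheticSession:
    """Generate the full multi-animal session.

    A fixed ``config.seed`` yields byte-identical output. ``noise=False``
    produces the zero-noise study condition (identical animals, no jitter,
    noiseless EMG). ``emg_muscles`` restricts synthesis to a channel subset.
    """
    if profiles is None:
        profiles = config.perturbation_profiles or load_paper_effects()
    master = np.random.default_rng([config.seed, 0])
    animals = sample_animals(config.n_animals, config.belt_speed, master,
                             noise=noise)
    session = SyntheticSession(config=config, profiles=profiles)
    for i, params in enumerate(animals):
        rng = np.random.default_rng([config.seed, 1 + i])
        plan = make_baseline_plan(params, config, rng, noise=noise)
        stimuli = inject_stimuli(plan, profiles, config, rng)
        markers = synthesize_markers(plan, frame_rate=config.frame_rate,
                                     rng=rng)
        emg = None
        if with_emg:
            emg = synthesize_emg(plan, rate=config.emg_rate, rng=rng,
                                 muscles=emg_muscles)
        session.animals.append(AnimalRecording(
            params=params, plan=plan, markers=markers, emg=emg,
            stimuli=stimuli))
    return session


def write_session(session: SyntheticSession, out_dir: str | Path) -> None:
    """Write per-animal markers.csv, emg.h5, stimuli.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in session.animals:
        adir = out / rec.params.name
        adir.mkdir(exist_ok=True)
        write_marker_csv(rec.markers, adir / "markers.csv")
        if rec.emg is not None:
            write_emg(rec.emg, adir / "emg.h5")
        write_stimuli(rec.stimuli, adir / "stimuli.tsv")
        (adir / "truth.json").write_text(json.dumps({
            "animal": rec.params.name,
            "belt_speed": rec.params.belt_speed,
            "cycle_period": rec.params.cycle_period,
            "duty_factor": rec.params.duty_factor,
            "stimuli": rec.truth,
        }, indent=1))
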