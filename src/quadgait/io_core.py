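"""Readers, writers and domain containers for the gait-perturbation pipeline.

Conventions (all downstream modules rely on these):

* Units are SI throughout: meters, seconds. The horizontal axis ``x``
  increases in the animal's direction of travel; ``y = 0`` is the belt
  surface.
* Marker data are sampled uniformly at the video frame rate (60 Hz by
  default); EMG at 5000 Hz by default.
* Marker files use the motion-tracking CSV dialect with a 3-row header
  (scorer / bodyparts / coords); EMG files use HDF5 with one dataset per
  channel under ``/emg/<side>_<muscle>`` or a wide CSV; stimulus files are
  TSV with one row per stimulus train.

No other module parses files: everything downstream consumes the typed
containers defined here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("quadgait")

# ---------------------------------------------------------------------------
# Naming conventions
# ---------------------------------------------------------------------------

SIDES = ("left", "right")

#: the 12 tracked landmarks per side, proximal to distal, forelimb then hindlimb
FORE_LANDMARKS = ("scapula", "humerus", "elbow", "wrist", "mcp", "fore_toe")
HIND_LANDMARKS = ("iliac_crest", "trochanter", "knee", "malleolus", "mtp", "hind_toe")
LANDMARKS = FORE_LANDMARKS + HIND_LANDMARKS

#: the 10 recorded muscles; flexors burst during swing, extensors during stance
MUSCLES = ("BB", "BFA", "BFP", "ECU", "LG", "SRT", "SOL", "ST", "TRI", "VL")
FLEXOR_MUSCLES = ("SRT", "BFP", "ST", "BB")
EXTENSOR_MUSCLES = ("BFA", "VL", "LG", "SOL", "TRI", "ECU")
HIND_MUSCLES = ("BFA", "BFP", "LG", "SRT", "SOL", "ST", "VL")
FORE_MUSCLES = ("BB", "TRI", "ECU")

#: limb roles relative to the stimulated hindlimb
LIMB_ROLES = ("ipsi_hind", "contra_hind", "homo_fore", "diag_fore")

#: the four targeted phases of the ipsilateral step cycle
PHASES = ("mid_stance", "stance_to_swing", "mid_swing", "swing_to_stance")


def limb_roles_for(stim_side: str) -> dict[str, tuple[str, str]]:
    """Map each limb role to (side, girdle) given the stimulated hindlimb side."""
    if stim_side not in SIDES:
        raise ValueError(f"unknown side {stim_side!r}")
    other = "left" if stim_side == "right" else "right"
    return {
        "ipsi_hind": (stim_side, "hind"),
        "contra_hind": (other, "hind"),
        "homo_fore": (stim_side, "fore"),
        "diag_fore": (other, "fore"),
    }


def toe_marker(role_side: str, girdle: str) -> tuple[str, str]:
    return role_side, ("hind_toe" if girdle == "hind" else "fore_toe")


class FormatError(ValueError):
    """A file failed structural validation (missing columns, bad schema)."""


class SamplingError(ValueError):
    """Timestamps are not uniformly sampled at the declared rate."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusTrain:
    """Descriptor of one stimulation train.

    The nominal train duration is stored verbatim from the protocol and is
    deliberately not derived from pulse count and frequency.
    """

    n_pulses: int = 25
    pulse_width_ms: float = 0.2
    frequency_hz: float = 300.0
    nominal_train_duration_ms: float = 88.0
    intensity_mt: float = 1.2  # multiple of the motor threshold

    def __post_init__(self) -> None:
        for name in ("n_pulses", "pulse_width_ms", "frequency_hz",
                     "nominal_train_duration_ms", "intensity_mt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"train parameter {name} must be positive")


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus delivered to the superficial peroneal nerve of `limb` side."""

    onset: float  # s
    limb: str  # stimulated (ipsilateral) hindlimb side: "left"/"right"
    train: StimulusTrain = field(default_factory=StimulusTrain)

    def __post_init__(self) -> None:
        if self.limb not in SIDES:
            raise ValueError(f"unknown side {self.limb!r}")
        if not np.isfinite(self.onset):
            raise ValueError("stimulus onset must be finite")


@dataclass
class MarkerTrajectories:
    """Time-stamped 2-D landmark positions in the treadmill frame.

    ``landmarks`` maps ``(side, name)`` to an ``(n_frames, 2)`` float array of
    ``(x, y)`` in meters.
    """

    time: np.ndarray  # (n_frames,), s
    landmarks: dict[tuple[str, str], np.ndarray]
    frame_rate: float = 60.0
    animal: str = ""
    belt_speed: float = float("nan")  # m/s

    #: markers may dip slightly below the belt plane from jitter
    Y_TOLERANCE = -0.005

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.validate()

    @property
    def n_frames(self) -> int:
        return self.time.size

    def validate(self) -> None:
        if self.time.ndim != 1 or self.time.size < 2:
            raise SamplingError("need at least two marker frames")
        dt = np.diff(self.time)
        if np.any(np.abs(dt - 1.0 / self.frame_rate) > 1e-9):
            raise SamplingError(
                f"marker timestamps are not uniform at {self.frame_rate} Hz")
        for key, arr in self.landmarks.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.time.size, 2):
                raise FormatError(f"landmark {key} has shape {arr.shape}, "
                                  f"expected ({self.time.size}, 2)")
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"landmark {key} contains non-finite values")
            if np.any(arr[:, 1] < self.Y_TOLERANCE):
                raise FormatError(
                    f"landmark {key} penetrates the belt below {self.Y_TOLERANCE} m")
            self.landmarks[key] = arr

    def xy(self, side: str, name: str) -> np.ndarray:
        return self.landmarks[(side, name)]


@dataclass
class EMGRecording:
    """Multi-channel EMG, uniformly sampled, in arbitrary voltage units."""

    time: np.ndarray  # (n_samples,), s
    channels: dict[tuple[str, str], np.ndarray]  # (side, muscle) -> (n,) signal
    rate: float = 5000.0
    animal: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise SamplingError("need at least two EMG samples")
        dt = np.diff(self.time)
        if np.any(np.abs(dt - 1.0 / self.rate) > 1e-9):
            raise SamplingError(f"EMG timestamps are not uniform at {self.rate} Hz")
        for (side, muscle), sig in self.channels.items():
            if side not in SIDES:
                raise FormatError(f"unknown side {side!r}")
            if muscle not in MUSCLES:
                raise FormatError(f"unknown muscle {muscle!r}; expected one of {MUSCLES}")
            sig = np.asarray(sig, dtype=float)
            if sig.shape != self.time.shape:
                raise FormatError(f"channel {(side, muscle)} length mismatch")
            self.channels[(side, muscle)] = sig


@dataclass
class PerturbationProfile:
    """Phase-specific effect sizes injected into the stimulated cycle.

    The identity profile (all multipliers 1, all deltas 0, empty maps) leaves
    the cycle untouched. Multipliers are ratios stimulated/control; the maps
    are keyed by limb role or ``(limb_role, muscle)``.
    """

    #: duration multipliers on the stimulated cycle, per limb role
    swing_multiplier: dict[str, float] = field(default_factory=dict)
    stance_multiplier: dict[str, float] = field(default_factory=dict)
    cycle_multiplier: dict[str, float] = field(default_factory=dict)
    #: multiplicative gain on the ipsilateral swing apex height
    toe_height_gain: float = 1.0
    #: target ratio of the contra–homo diagonal support duration (stim/control)
    support_gain_contra_homo: float | None = None
    #: target ratio of step length at the touchdown closing the stimulated cycle
    step_length_ratio: dict[str, float] = field(default_factory=dict)
    #: multiplier on the minimum (most flexed) joint angle of the ipsi hindlimb
    min_angle_multiplier: dict[str, float] = field(default_factory=dict)
    #: EMG effects, keyed "limb_role/MUSCLE"
    emg_amplitude_gain: dict[str, float] = field(default_factory=dict)
    emg_duration_gain: dict[str, float] = field(default_factory=dict)
    #: apply carryover multipliers to the post cycle as well
    carryover: bool = False

    def __post_init__(self) -> None:
        for m in (self.swing_multiplier, self.stance_multiplier,
                  self.cycle_multiplier, self.step_length_ratio,
                  self.min_angle_multiplier, self.emg_amplitude_gain,
                  self.emg_duration_gain):
            for k, v in m.items():
                if v <= 0:
                    raise ValueError(f"multiplier {k}={v} must be positive")
        if self.toe_height_gain <= 0:
            raise ValueError("toe_height_gain must be positive")
        if self.support_gain_contra_homo is not None and self.support_gain_contra_homo <= 0:
            raise ValueError("support_gain_contra_homo must be positive")

    @classmethod
    def identity(cls) -> "PerturbationProfile":
        return cls()

    def is_identity(self) -> bool:
        return (not any(abs(v - 1) > 1e-12 for m in
                        (self.swing_multiplier, self.stance_multiplier,
                         self.cycle_multiplier, self.step_length_ratio,
                         self.min_angle_multiplier, self.emg_amplitude_gain,
                         self.emg_duration_gain) for v in m.values())
                and abs(self.toe_height_gain - 1) < 1e-12
                and self.support_gain_contra_homo is None)


@dataclass
class SessionConfig:
    """Study-level configuration of a (synthetic) recording session."""

    belt_speed: float = 0.4  # m/s, nominal; per-animal speeds vary around this
    frame_rate: float = 60.0  # Hz
    emg_rate: float = 5000.0  # Hz
    n_animals: int = 7
    cycles_per_animal: int = 230
    stim_every_cycles: tuple[int, int] = (5, 6)
    stimuli_per_phase: int = 10
    phase_targets: tuple[str, ...] = PHASES
    seed: int = 0
    perturbation_profiles: dict[str, PerturbationProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.belt_speed <= 0:
            raise ValueError("belt_speed must be positive")
        if self.frame_rate <= 0 or self.emg_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.stimuli_per_phase < 1:
            raise ValueError("stimuli_per_phase must be >= 1")
        if self.n_animals < 1 or self.cycles_per_animal < 3:
            raise ValueError("need at least 1 animal and 3 cycles")
        lo, hi = self.stim_every_cycles
        if not (2 <= lo <= hi):
            raise ValueError("stim_every_cycles must be an increasing range >= 2")
        for p in self.phase_targets:
            if p not in PHASES:
                raise ValueError(f"unknown phase target {p!r}")


# ---------------------------------------------------------------------------
# Marker CSV (3-row header: scorer / bodyparts / coords)
# ---------------------------------------------------------------------------

_SCORER = "quadgait"


def write_marker_csv(markers: MarkerTrajectories, path: str | Path) -> None:
    """Write markers in the tracking-CSV dialect plus a JSON metadata sidecar."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {}
    for (side, name), arr in markers.landmarks.items():
        body = f"{side}_{name}"
        cols[f"{body}|x"] = arr[:, 0]
        cols[f"{body}|y"] = arr[:, 1]
    bodyparts = [c.split("|")[0] for c in cols]
    coords = [c.split("|")[1] for c in cols]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("scorer," + ",".join([_SCORER] * len(cols)) + "\n")
        fh.write("bodyparts," + ",".join(bodyparts) + "\n")
        fh.write("coords," + ",".join(coords) + "\n")
        data = np.column_stack(list(cols.values()))
        for i in range(markers.n_frames):
            fh.write(str(i) + "," + ",".join(format(v, ".12g") for v in data[i]) + "\n")
    meta = {
        "frame_rate": markers.frame_rate,
        "animal": markers.animal,
        "belt_speed": markers.belt_speed,
        "t0": float(markers.time[0]),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))


def read_marker_csv(path: str | Path,
                    frame_rate: float | None = None,
                    required: tuple[str, ...] = LANDMARKS) -> MarkerTrajectories:
    """Read a tracking-dialect marker CSV into :class:`MarkerTrajectories`.

    Raises :class:`FormatError` naming the first missing required landmark.
    Unknown landmarks are preserved and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    rate = frame_rate if frame_rate is not None else meta.get("frame_rate", 60.0)

    with open(path, encoding="utf-8") as fh:
        header = [next(fh).rstrip("\n").split(",") for _ in range(3)]
    if header[0][0] != "scorer" or header[1][0] != "bodyparts" or header[2][0] != "coords":
        raise FormatError(f"{path}: expected 3-row scorer/bodyparts/coords header")
    bodyparts = header[1][1:]
    coords = header[2][1:]
    data = np.loadtxt(path, delimiter=",", skiprows=3, ndmin=2)
    values = data[:, 1:]
    if values.shape[1] != len(bodyparts):
        raise FormatError(f"{path}: column count does not match header")

    landmarks: dict[tuple[str, str], np.ndarray] = {}
    for body in dict.fromkeys(bodyparts):
        side, _, name = body.partition("_")
        if side not in SIDES:
            raise FormatError(f"{path}: cannot parse bodypart {body!r}")
        ix = [i for i, (b, c) in enumerate(zip(bodyparts, coords)) if b == body and c == "x"]
        iy = [i for i, (b, c) in enumerate(zip(bodyparts, coords)) if b == body and c == "y"]
        if len(ix) != 1 or len(iy) != 1:
            raise FormatError(f"{path}: bodypart {body!r} lacks an x/y column pair")
        landmarks[(side, name)] = np.column_stack([values[:, ix[0]], values[:, iy[0]]])
        if name not in LANDMARKS:
            logger.warning("%s: unknown landmark %r preserved", path, body)

    for side in SIDES:
        for name in required:
            if (side, name) not in landmarks:
                raise FormatError(f"{path}: missing required landmark {side}_{name}")

    t0 = meta.get("t0", 0.0)
    time = t0 + np.arange(data.shape[0]) / rate
    return MarkerTrajectories(time=time, landmarks=landmarks, frame_rate=rate,
                              animal=meta.get("animal", ""),
                              belt_speed=meta.get("belt_speed", float("nan")))


# ---------------------------------------------------------------------------
# EMG HDF5 / CSV
# ---------------------------------------------------------------------------


def write_emg(emg: EMGRecording, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            grp = f.create_group("emg")
            grp.attrs["rate"] = emg.rate
            grp.attrs["units"] = "V"
            grp.attrs["animal"] = emg.animal
            grp.attrs["t0"] = float(emg.time[0])
            for (side, muscle), sig in emg.channels.items():
                grp.create_dataset(f"{side}_{muscle}", data=sig)
    elif path.suffix == ".csv":
        df = pd.DataFrame({"time_s": emg.time})
        for (side, muscle), sig in emg.channels.items():
            df[f"{side}_{muscle}"] = sig
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        raise FormatError(f"unsupported EMG format {path.suffix!r}")


def read_emg(path: str | Path, rate: float | None = None) -> EMGRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            grp = f["emg"]
            r = float(grp.attrs["rate"])
            t0 = float(grp.attrs.get("t0", 0.0))
            animal = str(grp.attrs.get("animal", ""))
            channels = {}
            n = None
            for key in grp:
                side, _, muscle = key.partition("_")
                channels[(side, muscle)] = np.asarray(grp[key], dtype=float)
                n = channels[(side, muscle)].size
        time = t0 + np.arange(n) / r
        return EMGRecording(time=time, channels=channels, rate=r, animal=animal)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise FormatError(f"{path}: EMG CSV needs a time_s column")
        time = df["time_s"].to_numpy()
        r = rate if rate is not None else 1.0 / float(np.median(np.diff(time)))
        channels = {}
        for col in df.columns:
            if col == "time_s":
                continue
            side, _, muscle = col.partition("_")
            channels[(side, muscle)] = df[col].to_numpy(dtype=float)
        n = time.size
        t0 = time[0]
        return EMGRecording(time=t0 + np.arange(n) / r, channels=channels,
                            rate=r)
    raise FormatError(f"unsupported EMG format {path.suffix!r}")


# ---------------------------------------------------------------------------
# Stimuli TSV
# ---------------------------------------------------------------------------

_STIM_COLUMNS = ["onset_s", "side", "n_pulses", "pulse_width_ms",
                 "frequency_hz", "train_duration_ms", "intensity_mt"]


def write_stimuli(stimuli: list[StimulusEvent], path: str | Path) -> None:
    rows = [{
        "onset_s": s.onset, "side": s.limb,
        "n_pulses": s.train.n_pulses, "pulse_width_ms": s.train.pulse_width_ms,
        "frequency_hz": s.train.frequency_hz,
        "train_duration_ms": s.train.nominal_train_duration_ms,
        "intensity_mt": s.train.intensity_mt,
    } for s in stimuli]
    pd.DataFrame(rows, columns=_STIM_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def read_stimuli(path: str | Path) -> list[StimulusEvent]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return []
    missing = [c for c in ("onset_s", "side") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing stimulus columns {missing}")
    out = []
    for _, row in df.iterrows():
        train = StimulusTrain(
            n_pulses=int(row.get("n_pulses", 25)),
            pulse_width_ms=float(row.get("pulse_width_ms", 0.2)),
            frequency_hz=float(row.get("frequency_hz", 300.0)),
            nominal_train_duration_ms=float(row.get("train_duration_ms", 88.0)),
            intensity_mt=float(row.get("intensity_mt", 1.2)),
        )
        out.append(StimulusEvent(onset=float(row["onset_s"]), limb=str(row["side"]),
                                 train=train))
    return out


# ---------------------------------------------------------------------------
# Config YAML
# ---------------------------------------------------------------------------


def _profile_to_dict(p: PerturbationProfile) -> dict:
    d = asdict(p)
    return d


def profile_from_dict(d: Mapping) -> PerturbationProfile:
    return PerturbationProfile(**dict(d))


def write_config(config: SessionConfig, path: str | Path) -> None:
    d = asdict(config)
    d["stim_every_cycles"] = list(config.stim_every_cycles)
    d["phase_targets"] = list(config.phase_targets)
    d["perturbation_profiles"] = {
        k: _profile_to_dict(v) for k, v in config.perturbation_profiles.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path: str | Path) -> SessionConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = yaml.safe_load(path.read_text()) or {}
    if "perturbation_profiles" in d:
        d["perturbation_profiles"] = {
            k: profile_from_dict(v) for k, v in d["perturbation_profiles"].items()}
    if "stim_every_cycles" in d:
        d["stim_every_cycles"] = tuple(d["stim_every_cycles"])
    if "phase_targets" in d:
        d["phase_targets"] = tuple(d["phase_targets"])
    return SessionConfig(**d)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
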