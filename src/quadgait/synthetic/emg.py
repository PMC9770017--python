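"""EMG synthesis: phase-gated amplitude-modulated noise per muscle.

Each channel is a band-limited (30-1000 Hz) Gaussian carrier under a
phase-gated envelope: flexors burst during their limb's swing, extensors
during stance. The envelope is a flat-topped Tukey window (5% cosine ramps)
whose amplitude and duration can be scaled per cycle by the perturbation
plan; a second, independent carrier provides the unmodulated baseline noise
at the configured burst-to-noise SNR.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..io_core import (EMGRecording, EXTENSOR_MUSCLES, HIND_MUSCLES,
                       MUSCLES, limb_roles_for)
from .perturb import SessionPlan

TUKEY_ALPHA = 0.1  # fraction of the gate spent in the two cosine ramps
EMG_BAND = (30.0, 1000.0)  # Hz


def bandlimited_noise(n: int, rate: float, rng: np.random.Generator
                      ) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to the EMG passband."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, EMG_BAND, btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / np.std(x)


def _tukey(tau: np.ndarray, alpha: float = TUKEY_ALPHA) -> np.ndarray:
    """Flat-topped window on [0, 1] with cosine ramps of width alpha/2."""
    env = np.ones_like(tau)
    half = alpha / 2.0
    lo = tau < half
    hi = tau > 1.0 - half
    env[lo] = np.sin(np.pi * tau[lo] / alpha) ** 2
    env[hi] = np.sin(np.pi * (1.0 - tau[hi]) / alpha) ** 2
    env[(tau < 0) | (tau > 1)] = 0.0
    return env


def muscle_role(side: str, muscle: str, stim_side: str) -> str:
    """Limb role a muscle belongs to, given the stimulated side."""
    girdle = "hind" if muscle in HIND_MUSCLES else "fore"
    for role, (s, g) in limb_roles_for(stim_side).items():
        if s == side and g == girdle:
            return role
    raise ValueError(f"no role for {side} {muscle}")


def gate_windows(plan: SessionPlan, role: str, muscle: str
                 ) -> list[tuple[float, float, float]]:
    """(start, duration, amplitude gain) of each burst gate for a channel.

    Extensor gates span the stance phase, flexor gates the swing phase. A
    per-cycle duration gain rescales the gate from the animal's nominal
    sub-phase duration (anchored at the gate start); an amplitude gain
    scales the envelope height.
    """
    if muscle not in MUSCLES:
        raise ValueError(f"unknown muscle {muscle!r}")
    a = plan.animal
    ev = plan.events[role]
    is_ext = muscle in EXTENSOR_MUSCLES
    nominal = (a.duty_factor if is_ext else 1.0 - a.duty_factor) * a.cycle_period
    gains = plan.emg_gain.get((role, muscle), {})
    out = []
    for i in range(ev.shape[0] - 1):
        start = ev[i, 0] if is_ext else ev[i, 1]
        dur = (ev[i, 1] - ev[i, 0]) if is_ext else (ev[i + 1, 0] - ev[i, 1])
        amp_g, dur_g = gains.get(i, (1.0, 1.0))
        if dur_g != 1.0:
            dur = dur_g * nominal
        out.append((float(start), float(dur), float(amp_g)))
    return out


def synthesize_emg(plan: SessionPlan, rate: float = 5000.0,
                   rng: np.random.Generator | None = None,
                   muscles: tuple[str, ...] | None = None) -> EMGRecording:
    """Render all available channels of one animal."""
    a = plan.animal
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(plan.duration * rate))
    t = np.arange(n) / rate
    use = a.muscles if muscles is None else tuple(
        m for m in muscles if m in a.muscles)
    channels: dict[tuple[str, str], np.ndarray] = {}
    roles = limb_roles_for(plan.stim_side)
    side_of = {role: s for role, (s, _) in roles.items()}
    for muscle in use:
        for role in roles:
            side, girdle = roles[role]
            if (muscle in HIND_MUSCLES) != (girdle == "hind"):
                continue
            amp = a.emg_amplitude[muscle]
            env = np.zeros(n)
            for start, dur, amp_g in gate_windows(plan, role, muscle):
                i0 = max(0, int(np.ceil(start * rate)))
                i1 = min(n, int(np.floor((start + dur) * rate)) + 1)
                if i1 <= i0:
                    continue
                tau = (t[i0:i1] - start) / dur
                env[i0:i1] = np.maximum(env[i0:i1], amp * amp_g * _tukey(tau))
            sig = env * bandlimited_noise(n, rate, rng)
            if np.isfinite(a.emg_snr):
                sig = sig + (amp / a.emg_snr) * bandlimited_noise(n, rate, rng)
            channels[(side_of[role], muscle)] = sig
    return EMGRecording(time=t, channels=channels, rate=rate, animal=a.name)
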