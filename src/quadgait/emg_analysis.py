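"""EMG filtering, burst detection and burst quantification.

The processing chain mirrors standard locomotor EMG practice: zero-phase
30-1000 Hz band-pass, full-wave rectification, a smooth envelope for burst
detection, and burst metrics computed on the rectified band-passed signal
(mean amplitude = rectified integral over the burst divided by its
duration). Burst amplitudes are normalized to the control-cycle burst of the
same muscle and triad and expressed as a percentage.

Burst scoring in the source protocol was visual; here a double-threshold
detector on the envelope replaces it, with every constant exposed as a
parameter so expert-scored overrides remain possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


def bandpass_filter(raw: np.ndarray, rate: float,
                    band: tuple[float, float] = (30.0, 1000.0),
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    if rate <= 2.0 * band[1]:
        raise ValueError(f"sampling rate {rate} Hz too low for a "
                         f"{band[1]} Hz upper cutoff")
    sos = sps.butter(order, band, btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(raw, float))


def envelope(filtered: np.ndarray, rate: float,
             cutoff: float = 50.0, order: int = 4) -> np.ndarray:
    """Full-wave rectification followed by a zero-phase low-pass."""
    sos = sps.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.abs(np.asarray(filtered, float)))


@dataclass(frozen=True)
class BurstParams:
    k_mad: float = 3.0          # upper threshold: baseline median + k*MAD
    min_burst_s: float = 0.02   # sustained time above the upper threshold
    min_gap_s: float = 0.02     # sub-threshold gaps shorter than this merge
    baseline_quantile: float = 0.25  # seed region for the baseline statistics
    edge_fraction: float = 0.25  # burst-relative envelope level for the edges


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    stops = np.nonzero(~padded[1:] & padded[:-1])[0]
    return list(zip(starts, stops))


def _detect(env: np.ndarray, rate: float, thr_hi: float, thr_lo: float,
            params: BurstParams) -> list[tuple[int, int]]:
    min_burst = max(1, int(round(params.min_burst_s * rate)))
    min_gap = max(1, int(round(params.min_gap_s * rate)))
    segs = _runs(env > thr_lo)
    # merge segments separated by brief sub-threshold dips
    merged: list[list[int]] = []
    for a, b in segs:
        if merged and a - merged[-1][1] < min_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        hi = env[a:b] > thr_hi
        best = max((r[1] - r[0] for r in _runs(hi)), default=0)
        if best >= min_burst:
            out.append((a, b))
    return out


def _refine_edges(env: np.ndarray, a: int, b: int,
                  fraction: float) -> tuple[int, int]:
    """Trim a detected burst to where the envelope crosses a burst-relative
    level (default half the burst's median height).

    The zero-phase envelope smears burst edges symmetrically, so the
    mid-height crossing localizes the true edge; being burst-relative, the
    trim does not depend on the burst's amplitude.
    """
    level = fraction * float(np.median(env[a:b]))
    inside = np.nonzero(env[a:b] >= level)[0]
    if inside.size < 2:
        return a, b
    return a + int(inside[0]), a + int(inside[-1]) + 1


def burst_thresholds(env: np.ndarray, rate: float,
                     params: BurstParams = BurstParams()
                     ) -> tuple[float, float]:
    """Robust (upper, lower) detection thresholds for one channel.

    Baseline statistics (median + MAD) are computed over non-burst samples,
    seeded from the lowest-quantile region and iterated twice so bursts do
    not contaminate the baseline regardless of their duty cycle.
    """
    env = np.asarray(env, float)
    mask = env <= np.quantile(env, params.baseline_quantile)
    thr_hi = thr_lo = np.inf
    for _ in range(2):
        base = env[mask]
        med = float(np.median(base))
        # MAD scaled to a Gaussian sigma so k is in noise-sd units
        mad = 1.4826 * float(np.median(np.abs(base - med)))
        thr_hi = med + params.k_mad * mad
        thr_lo = med + 0.5 * params.k_mad * mad
        in_burst = np.zeros(env.size, dtype=bool)
        for a, b in _detect(env, rate, thr_hi, thr_lo, params):
            in_burst[a:b] = True
        mask = ~in_burst
        if not np.any(mask):  # envelope entirely above threshold
            break
    return thr_hi, thr_lo


def detect_bursts(time: np.ndarray, env: np.ndarray, rate: float,
                  cycle_windows: list[tuple[float, float]],
                  params: BurstParams = BurstParams()
                  ) -> list[tuple[float, float] | None]:
    """At most one burst (onset, offset) per cycle window.

    Bursts are detected over the whole channel and assigned to the window
    containing their onset, so a burst outlasting its cycle keeps its true
    offset. When several bursts start in one window the longest is retained.
    If the envelope never returns to baseline the full window is returned
    as a single burst (a degenerate but explicit answer).
    """
    time = np.asarray(time, float)
    env = np.asarray(env, float)
    thr_hi, thr_lo = burst_thresholds(env, rate, params)
    if not np.isfinite(thr_hi) or np.all(env > thr_lo):
        return [(lo, hi) for lo, hi in cycle_windows]
    bursts = []
    for a, b in _detect(env, rate, thr_hi, thr_lo, params):
        a, b = _refine_edges(env, a, b, params.edge_fraction)
        bursts.append((time[a], time[min(b, time.size - 1)]))
    onsets = np.array([b[0] for b in bursts]) if bursts else np.empty(0)
    out: list[tuple[float, float] | None] = []
    for lo, hi in cycle_windows:
        sel = [bursts[i] for i in np.nonzero((onsets >= lo) & (onsets < hi))[0]]
        if not sel:
            out.append(None)
        else:
            out.append(max(sel, key=lambda b: b[1] - b[0]))
    return out


@dataclass(frozen=True)
class EMGBurst:
    muscle: str
    side: str
    onset: float
    offset: float
    mean_amplitude: float
    normalized_amplitude: float | None = None  # % of the control-cycle mean

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("burst onset must precede its offset")
        if self.mean_amplitude < 0:
            raise ValueError("mean amplitude must be non-negative")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def burst_metrics(time: np.ndarray, rectified: np.ndarray,
                  burst: tuple[float, float], muscle: str = "", side: str = "",
                  control_mean: float | None = None) -> EMGBurst:
    """Mean rectified amplitude over the burst, optionally normalized.

    ``control_mean`` is the control-cycle mean amplitude of the same muscle;
    normalization fails explicitly if it is non-positive.
    """
    time = np.asarray(time, float)
    rectified = np.asarray(rectified, float)
    on, off = burst
    sel = (time >= on) & (time < off)
    if not np.any(sel):
        raise ValueError("burst interval contains no samples")
    mean_amp = float(np.mean(rectified[sel]))
    normalized = None
    if control_mean is not None:
        if control_mean <= 0:
            raise ValueError("control-cycle mean amplitude must be positive "
                             "for normalization")
        normalized = 100.0 * mean_amp / control_mean
    return EMGBurst(muscle=muscle, side=side, onset=float(on), offset=float(off),
                    mean_amplitude=mean_amp, normalized_amplitude=normalized)
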