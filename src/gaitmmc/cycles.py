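"""Gait-event detection, cycle segmentation and time normalization.

Cycles are defined per system by that system's own event stream: minima of
the knee-flexion waveform for the markerless pipeline, upward GRF threshold
crossings (heel strikes) for the force-plate reference.  Each inter-event
interval is linearly resampled onto a fixed 0–100 % phase grid, and the
discrete parameters (max, min, ROM) are per-cycle extrema averaged across
cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from gaitmmc.types import AngleWaveform, GrfSeries, ValidationError


@dataclass
class EventList:
    """Strictly increasing gait-event times, seconds."""

    times: np.ndarray
    source: str  # {"knee_min", "heel_strike"}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size < 2:
            raise ValidationError("need at least 2 events to define a cycle")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("event times must be strictly increasing")
        if self.source not in ("knee_min", "heel_strike"):
            raise ValidationError(f"unknown event source {self.source!r}")


@dataclass
class NormalizedCycleSet:
    """Per-cycle angle vectors on a common 0–100 % phase grid."""

    phase_pct: np.ndarray  # (n_points,)
    cycles: np.ndarray  # (n_cycles, n_points), degrees

    def __post_init__(self) -> None:
        self.phase_pct = np.asarray(self.phase_pct, dtype=float)
        self.cycles = np.atleast_2d(np.asarray(self.cycles, dtype=float))
        if self.cycles.shape[1] != self.phase_pct.size:
            raise ValidationError("cycle vectors must match the phase grid length")

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.cycles.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.cycles.std(axis=0, ddof=1) if self.n_cycles > 1 else np.zeros_like(self.phase_pct)


@dataclass
class DiscreteGaitParams:
    """Per-trial averaged extrema of one joint angle, degrees."""

    joint: str
    max: float
    min: float
    rom: float


def estimate_cycle_duration(wave: AngleWaveform, max_lag_s: float = 2.5) -> float:
    """Dominant period of a (roughly periodic) waveform via autocorrelation."""
    v = wave.values - wave.values.mean()
    n = v.size
    ac = np.correlate(v, v, mode="full")[n - 1 :]
    max_lag = min(int(max_lag_s * wave.sample_rate), n - 1)
    lo = max(int(0.3 * wave.sample_rate), 2)  # ignore the zero-lag peak
    if max_lag <= lo:
        raise ValidationError("waveform too short to estimate a cycle duration")
    peaks, _ = find_peaks(ac[lo:max_lag])
    if peaks.size == 0:
        raise ValidationError("no periodicity found; cannot estimate cycle duration")
    # bimodal waveforms (e.g. knee flexion) put a secondary autocorrelation
    # peak at half the stride; the stride itself is the strongest peak
    best = peaks[np.argmax(ac[lo:max_lag][peaks])]
    return float((best + lo) / wave.sample_rate)


def detect_knee_min_events(
    knee: AngleWaveform,
    expected_cycle_s: float | None = None,
    min_separation_factor: float = 0.6,
) -> EventList:
    """Cycle starts at local minima of knee flexion.

    Minima must be separated by at least ``min_separation_factor`` times the
    expected cycle duration (estimated by autocorrelation when not given).
    """
    if expected_cycle_s is None:
        expected_cycle_s = estimate_cycle_duration(knee)
    if expected_cycle_s <= 0:
        raise ValidationError("expected_cycle_s must be positive")
    distance = max(int(min_separation_factor * expected_cycle_s * knee.sample_rate), 1)
    if np.ptp(knee.values) < 1e-9:
        raise ValidationError("constant waveform: no knee-flexion minima")
    idx, _ = find_peaks(-knee.values, distance=distance)
    if idx.size < 2:
        raise ValidationError("fewer than 2 knee-flexion minima found")
    # depth gate: the knee waveform has a secondary (midstance) valley well
    # above the terminal-swing minimum; a partial leading/trailing cycle can
    # surface it as a spurious trough, so discard troughs much shallower
    # than the median trough
    depths = knee.values[idx]
    med = np.median(depths)
    mad = np.median(np.abs(depths - med))
    keep = depths <= med + max(2.0, 5.0 * mad)
    if keep.sum() >= 2:
        idx = idx[keep]
    # sub-sample refinement: parabola through the trough and its neighbours;
    # at 30 Hz the raw sample grid alone quantizes cycle starts by ±17 ms
    times = knee.timestamps[idx].copy()
    v = knee.values
    interior = (idx > 0) & (idx < v.size - 1)
    i = idx[interior]
    denom = v[i - 1] - 2 * v[i] + v[i + 1]
    ok = denom > 1e-12
    shift = np.zeros(i.size)
    shift[ok] = 0.5 * (v[i - 1] - v[i + 1])[ok] / denom[ok]
    shift = np.clip(shift, -0.5, 0.5)
    times[interior] = knee.timestamps[i] + shift / knee.sample_rate
    return EventList(times=times, source="knee_min")


def detect_heel_strikes(
    grf: GrfSeries,
    threshold_n: float = 20.0,
    refractory_s: float = 0.3,
) -> EventList:
    """Heel strikes as upward threshold crossings of the vertical GRF.

    Crossing times are refined by linear interpolation between the samples
    bracketing the threshold; crossings closer than ``refractory_s`` to the
    previous one are ignored.
    """
    if threshold_n <= 0:
        raise ValidationError("threshold must be positive")
    f = grf.vertical_force
    above = f >= threshold_n
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if rising.size == 0:
        raise ValidationError("no threshold crossings in GRF")
    times = []
    last = -np.inf
    for i in rising:
        frac = (threshold_n - f[i - 1]) / (f[i] - f[i - 1])
        t = grf.timestamps[i - 1] + frac / grf.sample_rate
        if t - last >= refractory_s:
            times.append(t)
            last = t
    if len(times) < 2:
        raise ValidationError("fewer than 2 heel strikes detected")
    return EventList(times=np.asarray(times), source="heel_strike")


def segment_and_normalize(
    wave: AngleWaveform,
    events: EventList,
    n: int = 101,
) -> NormalizedCycleSet:
    """Resample each inter-event interval to ``n`` points spanning 0–100 %.

    Partial leading/trailing cycles (outside the event span) are discarded.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    t = wave.timestamps
    if events.times[0] < t[0] - 1e-9 or events.times[-1] > t[-1] + 1e-9:
        raise ValidationError("event outside waveform support")
    phase = np.linspace(0.0, 1.0, n)
    cycles = []
    for start, stop in zip(events.times[:-1], events.times[1:]):
        t_cycle = start + phase * (stop - start)
        cycles.append(np.interp(t_cycle, t, wave.values))
    return NormalizedCycleSet(phase_pct=phase * 100.0, cycles=np.asarray(cycles))


def discrete_params(cycles: NormalizedCycleSet, joint: str = "") -> DiscreteGaitParams:
    """Average of per-cycle extrema (not extrema of the averaged curve)."""
    if cycles.n_cycles < 1:
        raise ValidationError("need at least one cycle")
    cmax = float(cycles.cycles.max(axis=1).mean())
    cmin = float(cycles.cycles.min(axis=1).mean())
    return DiscreteGaitParams(joint=joint, max=cmax, min=cmin, rom=cmax - cmin)


def discrete_params_of_mean(cycles: NormalizedCycleSet, joint: str = "") -> DiscreteGaitParams:
    """Alternative reading: extrema of the cycle-averaged curve."""
    m = cycles.mean
    return DiscreteGaitParams(
        joint=joint, max=float(m.max()), min=float(m.min()), rom=float(m.max() - m.min())
    )
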