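"""Action-potential detection and summary features.

Beats are delimited by the time of maximum upstroke velocity (dV/dt_max),
located around rising threshold crossings at -20 mV (the two detectors
cross-validate each other). Features follow the conventions stated in the
package documentation: cycle length is the mean inter-upstroke interval,
MDP the mean per-beat minimum, and APD50/APD90 are measured from the
upstroke (dV/dt_max instant) to 50%/90% repolarization of that beat's
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .engine import SimulationTrace

__all__ = [
    "Beat", "APFeatureSet", "InsufficientBeatsError",
    "detect_beats", "compute_features", "delta_features",
]

THRESHOLD_MV = -20.0


class InsufficientBeatsError(ValueError):
    """Fewer than two upstrokes in the trace."""


@dataclass(frozen=True)
class Beat:
    """One detected beat: upstroke (dV/dt_max) time and index."""

    upstroke_time: float
    upstroke_index: int


@dataclass(frozen=True)
class APFeatureSet:
    """Per-run AP summary, averaged over the analyzed beats.

    Invariants: ``amplitude == overshoot - mdp`` and
    ``rate == 60000 / cycle_length`` hold exactly by construction.
    """

    cycle_length: float        # ms
    rate: float                # beats/min
    mdp: float                 # mV
    overshoot: float           # mV
    amplitude: float           # mV
    apd50: float               # ms
    apd90: float               # ms
    dvdt_max: float            # mV/ms
    cai_diastolic: float | None  # mM
    cai_systolic: float | None   # mM
    n_beats_analyzed: int
    converged: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def detect_beats(trace: SimulationTrace) -> list[Beat]:
    """Locate upstrokes in a trace.

    Rising -20 mV crossings seed the search; the upstroke time is the local
    dV/dt maximum near each crossing. Raises ``InsufficientBeatsError``
    when fewer than two upstrokes exist.
    """
    vm = np.asarray(trace.vm, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    if vm.size < 3:
        raise InsufficientBeatsError("trace too short")
    dt = trace.dt
    dvdt = np.gradient(vm, dt)

    above = vm >= THRESHOLD_MV
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    if crossings.size < 2:
        raise InsufficientBeatsError(
            f"fewer than 2 upstrokes detected ({crossings.size} crossings of "
            f"{THRESHOLD_MV} mV)")

    half_window = max(1, int(round(40.0 / dt)))  # +-40 ms around the crossing
    beats: list[Beat] = []
    for c in crossings:
        lo = max(0, c - half_window)
        hi = min(len(vm), c + half_window)
        idx = lo + int(np.argmax(dvdt[lo:hi]))
        if beats and idx == beats[-1].upstroke_index:
            continue
        beats.append(Beat(upstroke_time=float(t[idx]), upstroke_index=idx))
    if len(beats) < 2:
        raise InsufficientBeatsError("fewer than 2 distinct upstrokes")
    return beats


def _repol_time(t, vm, start, stop, level):
    """First time in [start, stop) at which vm falls below `level`."""
    seg = vm[start:stop]
    below = np.nonzero(seg <= level)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return float(t[start])
    # linear interpolation between samples
    v0, v1 = seg[i - 1], seg[i]
    f = (v0 - level) / (v0 - v1) if v1 != v0 else 0.0
    return float(t[start + i - 1] + f * (t[start + i] - t[start + i - 1]))


def compute_features(
    trace: SimulationTrace,
    beats: list[Beat] | None = None,
    *,
    n_avg: int = 5,
) -> APFeatureSet:
    """AP features averaged over the last `n_avg` complete beats."""
    if beats is None:
        beats = detect_beats(trace)
    if len(beats) < 2:
        raise InsufficientBeatsError("need >= 2 complete beats")
    vm = np.asarray(trace.vm, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    dvdt = np.gradient(vm, trace.dt)

    intervals = np.diff([b.upstroke_time for b in beats])
    # per-beat windows [upstroke_k, upstroke_{k+1})
    windows = [(beats[k].upstroke_index, beats[k + 1].upstroke_index)
               for k in range(len(beats) - 1)]
    windows = windows[-n_avg:]
    intervals = intervals[-len(windows):]

    mdps, peaks, apd50s, apd90s, dvdt_maxes = [], [], [], [], []
    cai_min, cai_max = [], []
    for (a, b) in windows:
        seg = vm[a:b]
        peak = float(seg.max())
        mdp = float(seg.min())
        peaks.append(peak)
        mdps.append(mdp)
        dvdt_maxes.append(float(dvdt[a:b].max()))
        amp = peak - mdp
        peak_i = a + int(np.argmax(seg))
        t50 = _repol_time(t, vm, peak_i, b, peak - 0.5 * amp)
        t90 = _repol_time(t, vm, peak_i, b, peak - 0.9 * amp)
        t_up = t[a]
        apd50s.append((t50 - t_up) if t50 is not None else np.nan)
        apd90s.append((t90 - t_up) if t90 is not None else np.nan)
        if trace.cai is not None:
            cai_min.append(float(trace.cai[a:b].min()))
            cai_max.append(float(trace.cai[a:b].max()))

    cl = float(np.mean(intervals))
    mdp = float(np.mean(mdps))
    overshoot = float(np.mean(peaks))
    return APFeatureSet(
        cycle_length=cl,
        rate=60000.0 / cl,
        mdp=mdp,
        overshoot=overshoot,
        amplitude=overshoot - mdp,
        apd50=float(np.nanmean(apd50s)),
        apd90=float(np.nanmean(apd90s)),
        dvdt_max=float(np.mean(dvdt_maxes)),
        cai_diastolic=float(np.mean(cai_min)) if cai_min else None,
        cai_systolic=float(np.mean(cai_max)) if cai_max else None,
        n_beats_analyzed=len(windows),
        converged=bool(trace.meta.get("converged", True)),
    )


def delta_features(control: APFeatureSet, treated: APFeatureSet) -> dict:
    """ISO-induced changes, on the scales used throughout the study.

    ``d_rate_pct`` is the percentage change of firing frequency,
    ``d_cl_pct`` the percentage *decrease* of cycle length (positive =
    faster), ``d_mdp_mv`` is treated minus control in mV (negative =
    hyperpolarization).
    """
    return {
        "d_rate_pct": (treated.rate / control.rate - 1.0) * 100.0,
        "d_cl_pct": (1.0 - treated.cycle_length / control.cycle_length) * 100.0,
        "d_mdp_mv": treated.mdp - control.mdp,
        "d_overshoot_mv": treated.overshoot - control.overshoot,
        "d_amplitude_mv": treated.amplitude - control.amplitude,
        "d_apd50_ms": treated.apd50 - control.apd50,
        "d_apd90_ms": treated.apd90 - control.apd90,
        "converged": bool(control.converged and treated.converged),
    }
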