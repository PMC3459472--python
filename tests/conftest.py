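"""Shared fixtures.

Integration tests share one ExperimentRunner per session so steady-state
runs (the expensive part) are computed once and reused; the runner uses a
shortened settling window, which is sufficient because each model's stored
initial state already lies on its control limit cycle.
"""

from __future__ import annotations

import numpy as np
import pytest

from isosan.engine import SimulationTrace
from isosan.experiments import ExperimentRunner


@pytest.fixture(scope="session")
def runner() -> ExperimentRunner:
    return ExperimentRunner(settle_ms=8000.0, analyze_ms=4000.0, output_dt=0.2)


@pytest.fixture(scope="session")
def control_features(runner):
    """Control (drug-free) steady-state features per model, computed once."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = runner.steady_features(name)
        return cache[name]

    return get


def make_synthetic_trace(period_ms=300.0, n_beats=6, dt=0.1,
                         mdp=-65.0, peak=20.0, t_shift=0.0):
    """Sawtooth-plus-spike waveform of exactly known period and extremes.

    Each cycle: a fast 5 ms upstroke from `mdp` to `peak`, a 100 ms linear
    repolarization back to `mdp`, then a slow linear diastolic ramp.
    """
    t = np.arange(0.0, n_beats * period_ms, dt)
    phase = (t + t_shift) % period_ms
    up, repol = 5.0, 100.0
    ramp_amp = 10.0
    vm = np.empty_like(t)
    rise = phase < up
    fall = (phase >= up) & (phase < up + repol)
    dia = ~(rise | fall)
    # half-cosine upstroke: smooth, with a unique dV/dt maximum mid-rise
    vm[rise] = mdp + ramp_amp + (peak - mdp - ramp_amp) * 0.5 * (
        1.0 - np.cos(np.pi * phase[rise] / up))
    vm[fall] = peak - (peak - mdp) * ((phase[fall] - up) / repol)
    vm[dia] = mdp + ramp_amp * ((phase[dia] - up - repol)
                                / (period_ms - up - repol))
    return SimulationTrace(time=t, vm=vm, states=vm[:, None],
                           state_labels=("v",))
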