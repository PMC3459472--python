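"""Stiff integration of SAN cell models to steady pacing.

SAN cells are autonomous oscillators: no stimulus protocol exists anywhere
in this engine, by design. The default steady-state protocol integrates a
settling window (transient discard) followed by an analysis window sampled
on a uniform grid, and reports beat-to-beat cycle-length convergence. A
model that stops firing is a scientific outcome ("pacemaking ceased"), not
an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models.base import CellModelSpec

__all__ = ["SimulationTrace", "SolverError", "run", "run_to_steady"]

#: Default solver settings (stiff-capable adaptive integration).
DEFAULT_RTOL = 1e-7
DEFAULT_ATOL = 1e-9
DEFAULT_METHOD = "LSODA"
DEFAULT_OUTPUT_DT = 0.1  # ms


class SolverError(RuntimeError):
    """Integration failed; carries the last valid time reached."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


@dataclass
class SimulationTrace:
    """Uniformly sampled simulation output.

    ``time`` in ms (strictly increasing, constant step), ``vm`` in mV,
    ``cai`` in mM (None for models without Ca2+ state), ``currents`` in nA,
    ``states`` the full state matrix (n_time x n_states).
    """

    time: np.ndarray
    vm: np.ndarray
    states: np.ndarray
    state_labels: tuple
    cai: np.ndarray | None = None
    currents: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self):
        """Tidy DataFrame: time plus one column per recorded series."""
        import pandas as pd

        data = {"time_ms": self.time, "vm_mv": self.vm}
        if self.cai is not None:
            data["cai_mm"] = self.cai
        for k, v in self.currents.items():
            data[f"{k}_na"] = v
        return pd.DataFrame(data)

    def write_csv(self, path, metadata: dict | None = None):
        """Write the trace as tidy CSV with a JSON metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        side = dict(self.meta)
        if metadata:
            side.update(metadata)
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def _integrate(model: CellModelSpec, y0, t_span, t_eval, rtol, atol, method):
    pvec = model.param_vector()
    fn = model.rhs_fn

    def f(t, y):
        return fn(t, y, pvec)

    sol = solve_ivp(
        f, t_span, y0, method=method, t_eval=t_eval,
        rtol=rtol, atol=atol, dense_output=False,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        last = float(sol.t[-1]) if sol.t.size else float(t_span[0])
        raise SolverError(
            f"integration of {model.name} failed at t={last:.3f} ms: "
            f"{sol.message}", last)
    return sol


def run(
    model: CellModelSpec,
    duration: float,
    output_dt: float = DEFAULT_OUTPUT_DT,
    *,
    y0=None,
    record_currents: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> SimulationTrace:
    """Integrate `model` for `duration` ms and sample every `output_dt` ms.

    Deterministic: identical settings give identical traces. Raises
    ``ValueError`` for non-positive duration/output_dt and ``SolverError``
    on integration failure.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0 ms")
    if output_dt <= 0:
        raise ValueError("output_dt must be > 0 ms")
    y0 = model.initial_state if y0 is None else np.asarray(y0, dtype=float)
    n = int(round(duration / output_dt))
    t_eval = np.arange(n + 1) * output_dt
    sol = _integrate(model, y0, (0.0, t_eval[-1]), t_eval, rtol, atol, method)
    states = sol.y.T
    cai = states[:, model.cai_index] if model.cai_index is not None else None
    trace = SimulationTrace(
        time=sol.t.copy(),
        vm=states[:, 0].copy(),
        states=states,
        state_labels=model.state_labels,
        cai=None if cai is None else cai.copy(),
        meta={
            "model": model.name,
            "duration_ms": float(duration),
            "output_dt_ms": float(output_dt),
            "rtol": rtol, "atol": atol, "method": method,
        },
    )
    if record_currents:
        trace.currents = extract_currents(model, trace)
    return trace


def extract_currents(model: CellModelSpec, trace: SimulationTrace) -> dict:
    """Named current series (nA) along a trace, including the summed i_k."""
    pvec = model.param_vector()
    vals = np.empty((len(trace.time), len(model.current_labels)))
    for i in range(len(trace.time)):
        vals[i] = model.currents_fn(trace.states[i], pvec)
    out = {lab: vals[:, j] for j, lab in enumerate(model.current_labels)}
    out["i_k"] = out["i_kr"] + out["i_ks"]
    if "i_f_na" in out:
        out["i_f"] = out["i_f_na"] + out["i_f_k"]
    return out


def run_to_steady(
    model: CellModelSpec,
    *,
    settle_ms: float = 20000.0,
    analyze_ms: float = 10000.0,
    max_beats: int = 400,
    cl_tolerance: float = 1e-3,
    output_dt: float = DEFAULT_OUTPUT_DT,
    record_currents: bool = False,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> SimulationTrace:
    """Integrate past the initial transient and return the analysis window.

    The settling window (default 20 s) is integrated coarsely and discarded;
    the analysis window (default 10 s) is returned at `output_dt`
    resolution. The trace metadata carries a convergence report:
    ``converged`` (successive cycle lengths within `cl_tolerance`,
    relative), ``ceased`` (fewer than 2 upstrokes detected: pacemaking
    stopped — a result, not an exception), and the measured cycle lengths.
    """
    from .features import detect_beats, InsufficientBeatsError

    if cl_tolerance <= 0:
        raise ValueError("cl_tolerance must be > 0")
    if max_beats < 2:
        raise ValueError("max_beats must be >= 2")

    # settle (coarse sampling; only the end state is kept)
    y = model.initial_state
    if settle_ms > 0:
        sol = _integrate(model, y, (0.0, settle_ms), np.array([0.0, settle_ms]),
                         rtol, atol, method)
        y = sol.y[:, -1]

    trace = run(model, analyze_ms, output_dt, y0=y,
                record_currents=record_currents,
                rtol=rtol, atol=atol, method=method)
    trace.meta["settle_ms"] = float(settle_ms)

    extra_rounds = 0
    while True:
        try:
            beats = detect_beats(trace)
        except InsufficientBeatsError:
            trace.meta.update(converged=False, ceased=True, cycle_lengths=[])
            return trace
        cls = np.diff([b.upstroke_time for b in beats])
        n_check = min(5, len(cls))
        tail = cls[-n_check:]
        converged = (len(cls) >= 2 and
                     float(np.max(np.abs(np.diff(tail) / tail[:-1]))) < cl_tolerance)
        total_beats = len(beats) + extra_rounds * max(len(beats), 1)
        if converged or total_beats >= max_beats or extra_rounds >= 8:
            trace.meta.update(
                converged=bool(converged), ceased=False,
                cycle_lengths=[float(c) for c in cls],
                n_beats=len(beats),
            )
            return trace
        # not yet periodic: continue from the end of the current window
        extra_rounds += 1
        trace = run(model, analyze_ms, output_dt, y0=trace.states[-1],
                    record_currents=record_currents,
                    rtol=rtol, atol=atol, method=method)
        trace.meta["settle_ms"] = float(settle_ms + extra_rounds * analyze_ms)
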