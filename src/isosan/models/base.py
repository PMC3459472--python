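"""Shared container for sinoatrial-node cell models.

A model is an autonomous ODE system ``dy/dt = f(y, p)`` with a fixed state
ordering, a named parameter table, and named membrane-current observables.
The right-hand side and the current extractor are pure compiled functions of
``(t, state, parameter-vector)`` so that integration is fast and the same
model object can be cheaply copied and re-parameterized (which is how the
isoprenaline layer operates).

Conventions: membrane potential in mV, time in ms, membrane currents in nA,
conductances in uS, capacitance in nF, concentrations in mM.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["CellModelSpec", "UnsupportedActionError"]


class UnsupportedActionError(KeyError):
    """An ISO action targets a parameter the model does not possess."""


@dataclass
class CellModelSpec:
    """A named, parameterized SAN cell model (autonomous ODE system)."""

    name: str
    family: str                      # "boyett" | "kurata"
    region: str                      # "central" | "peripheral"
    state_labels: tuple
    initial_state: np.ndarray
    param_names: tuple
    parameters: dict = field(repr=False)
    current_labels: tuple = field(repr=False)
    rhs_fn: Callable = field(repr=False)       # (t, y, pvec) -> dy
    currents_fn: Callable = field(repr=False)  # (y, pvec) -> currents (nA)
    cai_index: int | None = None     # index of bulk [Ca2+]_i in the state, if any

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if len(self.initial_state) != len(self.state_labels):
            raise ValueError("initial_state length does not match state_labels")
        if set(self.param_names) != set(self.parameters):
            raise ValueError("param_names and parameters table disagree")

    # -- construction helpers -------------------------------------------------
    def copy(self) -> "CellModelSpec":
        """Independent copy sharing the compiled functions."""
        new = _copy.copy(self)
        new.parameters = dict(self.parameters)
        new.initial_state = self.initial_state.copy()
        return new

    def param_vector(self) -> np.ndarray:
        return np.array([self.parameters[n] for n in self.param_names], dtype=float)

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    # -- evaluation -----------------------------------------------------------
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.rhs_fn(t, np.asarray(y, dtype=float), self.param_vector())

    def evaluate_currents(self, state) -> dict:
        """All membrane currents (nA) at `state`, plus the summed delayed
        rectifier ``i_k = i_kr + i_ks`` and the total membrane current.

        The reconstruction identity ``dV/dt == -i_tot / Cm`` holds to
        numerical precision (current bookkeeping is complete).
        """
        y = np.asarray(state, dtype=float)
        if y.shape != (self.n_states,):
            raise ValueError(
                f"state dimension {y.shape} does not match model "
                f"({self.n_states} states)"
            )
        vals = self.currents_fn(y, self.param_vector())
        out = dict(zip(self.current_labels, (float(v) for v in vals)))
        out["i_k"] = out["i_kr"] + out["i_ks"]
        if "i_f_na" in out:
            out["i_f"] = out["i_f_na"] + out["i_f_k"]
        out["i_tot"] = float(sum(vals))
        return out
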