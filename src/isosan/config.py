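"""Run-specification parsing, validation and serialization (YAML).

A run spec names the cell model, the ISO dose (with explicit unit), the
per-action switches, solver settings and output options. Unknown keys are
rejected with their key paths; units are normalized to the package's
internal conventions (nM, ms, mV). Every executed run can emit a resolved
copy of its spec for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .dose_response import IsoActionSet, IsoDoseParams, ACTION_NAMES
from .models import MODEL_NAMES

__all__ = ["RunSpec", "load_config", "save_config", "parse_dose"]


class ConfigError(ValueError):
    """Schema violation, reported with the offending key path."""


def parse_dose(value) -> float:
    """Parse a dose with unit suffix into nM.

    Accepts a bare number (interpreted as nM), or strings like
    ``"50 nM"``, ``"0.05 uM"``, ``"0.05 µM"``.
    """
    if isinstance(value, (int, float)):
        dose = float(value)
    else:
        s = str(value).strip().replace("µ", "u")
        parts = s.split()
        if len(parts) == 1:
            low = s.lower()
            if low.endswith("nm"):
                dose = float(low[:-2]) * 1.0
            elif low.endswith("um"):
                dose = float(low[:-2]) * 1e3
            else:
                dose = float(s)
        elif len(parts) == 2:
            num, unit = parts
            unit = unit.lower()
            if unit not in ("nm", "um"):
                raise ConfigError(f"dose unit must be nM or uM, got {unit!r}")
            dose = float(num) * (1.0 if unit == "nm" else 1e3)
        else:
            raise ConfigError(f"cannot parse dose {value!r}")
    if dose < 0:
        raise ConfigError("dose must be >= 0")
    return dose


@dataclass
class RunSpec:
    """Validated, unit-normalized run specification."""

    model: str
    dose_nm: float = 0.0
    actions: dict = field(default_factory=lambda: {a: True for a in ACTION_NAMES})
    dose_params: IsoDoseParams = field(default_factory=IsoDoseParams)
    settle_ms: float = 20000.0
    analyze_ms: float = 10000.0
    output_dt_ms: float = 0.1
    rtol: float = 1e-7
    atol: float = 1e-9
    method: str = "LSODA"

    def action_set(self) -> IsoActionSet:
        return IsoActionSet(
            dose=self.dose_nm,
            **{f"enable_{a}": bool(v) for a, v in self.actions.items()},
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dose_params"] = self.dose_params.to_dict()
        return d


_TOP_KEYS = {"model", "dose", "actions", "dose_params", "solver", "protocol"}


def _from_dict(raw: dict) -> RunSpec:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "model" not in raw:
        raise ConfigError("missing required key: model")
    model = str(raw["model"])
    if model not in MODEL_NAMES:
        raise ConfigError(
            f"model: unknown model {model!r}; valid: {', '.join(MODEL_NAMES)}")

    spec = RunSpec(model=model)
    if "dose" in raw:
        spec.dose_nm = parse_dose(raw["dose"])
    if "actions" in raw:
        acts = raw["actions"]
        if not isinstance(acts, dict):
            raise ConfigError("actions: must be a mapping of action -> bool")
        for k, v in acts.items():
            if k not in ACTION_NAMES:
                raise ConfigError(
                    f"actions.{k}: unknown action; valid: {', '.join(ACTION_NAMES)}")
            if not isinstance(v, bool):
                raise ConfigError(f"actions.{k}: must be true/false")
            spec.actions[k] = v
    if "dose_params" in raw:
        try:
            spec.dose_params = IsoDoseParams.from_dict(raw["dose_params"])
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"dose_params: {exc}") from exc
    solver = raw.get("solver", {})
    for key in set(solver) - {"rtol", "atol", "method"}:
        raise ConfigError(f"solver.{key}: unknown key")
    spec.rtol = float(solver.get("rtol", spec.rtol))
    spec.atol = float(solver.get("atol", spec.atol))
    spec.method = str(solver.get("method", spec.method))
    proto = raw.get("protocol", {})
    for key in set(proto) - {"settle_ms", "analyze_ms", "output_dt_ms"}:
        raise ConfigError(f"protocol.{key}: unknown key")
    spec.settle_ms = float(proto.get("settle_ms", spec.settle_ms))
    spec.analyze_ms = float(proto.get("analyze_ms", spec.analyze_ms))
    spec.output_dt_ms = float(proto.get("output_dt_ms", spec.output_dt_ms))
    if spec.output_dt_ms <= 0 or spec.analyze_ms <= 0 or spec.settle_ms < 0:
        raise ConfigError("protocol: windows must be positive (settle >= 0)")
    return spec


def load_config(path) -> RunSpec:
    """Load and validate a YAML run spec; defaults filled, units normalized."""
    text = Path(path).read_text()
    return _from_dict(yaml.safe_load(text) or {})


def save_config(spec: RunSpec, path) -> None:
    """Write a resolved spec; ``load_config(save_config(s)) == s``."""
    d = spec.to_dict()
    out = {
        "model": d.pop("model"),
        "dose": f"{d.pop('dose_nm')} nM",
        "actions": d.pop("actions"),
        "dose_params": d.pop("dose_params"),
        "solver": {"rtol": d.pop("rtol"), "atol": d.pop("atol"),
                   "method": d.pop("method")},
        "protocol": {"settle_ms": d.pop("settle_ms"),
                     "analyze_ms": d.pop("analyze_ms"),
                     "output_dt_ms": d.pop("output_dt_ms")},
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
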