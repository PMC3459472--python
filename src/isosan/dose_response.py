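"""Isoprenaline (ISO) concentration-response relations and their application.

Six saturating (Hill-type) curves describe the steady-state, dose-dependent
end-effects of beta-adrenergic stimulation on rabbit sinoatrial-node ionic
currents, as fitted to voltage-clamp data:

* fractional increase of the L-type Ca2+ conductance g_CaL,
* depolarizing shift of the I_f steady-state activation curve (mV),
* fractional increase of the delayed-rectifier conductances g_Kr and g_Ks,
* negative (leftward) shift of the I_Kr activation curve (mV),
* fractional increase of the I_Kr deactivation *rate* (tau_Kr is divided
  by 1 + d_tau),
* fractional increase of the sustained inward conductance g_st.

A seventh, dose-independent action rescales the sarcoplasmic-reticulum Ca2+
fluxes (maximal release x1.20, uptake x0.80) whenever ISO is present,
mimicking the CamKII-mediated enhancement of the Ca2+ transient.

All concentrations are in nM. Every curve is exactly zero at dose 0 and
equals half its maximum at its half-maximal concentration K_0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace, fields

__all__ = [
    "IsoDoseParams",
    "IsoActionSet",
    "ACTION_NAMES",
    "iso_fraction_ical",
    "iso_shift_if",
    "iso_fraction_ik",
    "iso_shift_ikr_activation",
    "iso_taukr_factor",
    "iso_fraction_ist",
    "iso_apply",
]

#: Version tag for the embedded best-fit constant table.
DOSE_PARAMS_VERSION = "1"


def _check_dose(dose: float) -> float:
    dose = float(dose)
    if dose < 0:
        raise ValueError(f"ISO concentration must be >= 0 nM, got {dose}")
    return dose


@dataclass(frozen=True)
class IsoDoseParams:
    """Best-fit constants of the six ISO concentration-response curves.

    Defaults are the published best-fit values; concentrations in nM,
    voltage shifts in mV, fractions dimensionless.
    """

    f_ca_max: float = 0.54      # max fractional increase of g_CaL
    k_ca: float = 7.0           # nM
    s_f_max: float = 9.62       # mV, max depolarizing shift of I_f activation
    k_f: float = 13.5           # nM
    n_f: float = 0.392          # Hill coefficient of the I_f shift
    f_k_max: float = 1.87       # max fractional increase of g_Kr (and g_Ks)
    k_gk: float = 19.0          # nM
    s_k_max: float = -15.0      # mV, max (negative) shift of I_Kr activation
    k_kacti: float = 7.5        # nM
    dtau_kr_max: float = 3.0    # max fractional increase of I_Kr deactivation rate
    k_taukr: float = 24.0       # nM
    f_st_max: float = 1.0       # max fractional increase of g_st
    k_st: float = 33.0          # nM
    sr_release_scale: float = 1.20  # SR maximal release multiplier under ISO
    sr_uptake_scale: float = 0.80   # SR uptake multiplier under ISO

    def __post_init__(self) -> None:
        for name in ("k_ca", "k_f", "k_gk", "k_kacti", "k_taukr", "k_st"):
            if getattr(self, name) <= 0:
                raise ValueError(f"half-maximal concentration {name} must be > 0")
        if self.n_f <= 0:
            raise ValueError("Hill coefficient n_f must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IsoDoseParams":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise KeyError(f"unknown IsoDoseParams keys: {sorted(unknown)}")
        return cls(**d)


#: The seven switchable ISO actions, in a fixed order.
ACTION_NAMES = (
    "ical", "if", "gk", "ikr_shift", "taukr", "ist", "ca_handling",
)


@dataclass(frozen=True)
class IsoActionSet:
    """An ISO concentration plus one enable switch per modelled action.

    With ``dose == 0`` the set is a no-op regardless of the flags; disabling
    a flag removes that action at any dose (the leave-one-out / only-one-in
    dissection experiments are expressed through these switches).
    """

    dose: float = 0.0  # nM
    enable_ical: bool = True
    enable_if: bool = True
    enable_gk: bool = True
    enable_ikr_shift: bool = True
    enable_taukr: bool = True
    enable_ist: bool = True
    enable_ca_handling: bool = True

    def __post_init__(self) -> None:
        _check_dose(self.dose)

    def enabled(self, action: str) -> bool:
        if action not in ACTION_NAMES:
            raise ValueError(
                f"unknown ISO action {action!r}; valid: {', '.join(ACTION_NAMES)}"
            )
        return bool(getattr(self, f"enable_{action}"))

    def with_only(self, keep: str) -> "IsoActionSet":
        """Copy with exactly one action enabled."""
        if keep not in ACTION_NAMES:
            raise ValueError(
                f"unknown ISO action {keep!r}; valid: {', '.join(ACTION_NAMES)}"
            )
        kw = {f"enable_{a}": (a == keep) for a in ACTION_NAMES}
        return replace(self, **kw)

    def without(self, omit: str) -> "IsoActionSet":
        """Copy with one action disabled."""
        if omit not in ACTION_NAMES:
            raise ValueError(
                f"unknown ISO action {omit!r}; valid: {', '.join(ACTION_NAMES)}"
            )
        return replace(self, **{f"enable_{omit}": False})

    def to_dict(self) -> dict:
        return asdict(self)


def _hill1(dose: float, fmax: float, k: float) -> float:
    # simple saturation (Hill coefficient 1)
    return fmax * dose / (k + dose)


def iso_fraction_ical(dose: float, params: IsoDoseParams | None = None) -> float:
    """Fractional increase of g_CaL at `dose` nM ISO (dimensionless)."""
    params = params or IsoDoseParams()
    return _hill1(_check_dose(dose), params.f_ca_max, params.k_ca)


def iso_shift_if(dose: float, params: IsoDoseParams | None = None) -> float:
    """Depolarizing shift of the I_f activation curve, in mV."""
    params = params or IsoDoseParams()
    dose = _check_dose(dose)
    if dose == 0.0:
        return 0.0
    dn = dose ** params.n_f
    return params.s_f_max * dn / (params.k_f ** params.n_f + dn)


def iso_fraction_ik(dose: float, params: IsoDoseParams | None = None) -> float:
    """Fractional increase of g_Kr and g_Ks (dimensionless)."""
    params = params or IsoDoseParams()
    return _hill1(_check_dose(dose), params.f_k_max, params.k_gk)


def iso_shift_ikr_activation(dose: float, params: IsoDoseParams | None = None) -> float:
    """Shift of the I_Kr steady-state activation curve, in mV (negative)."""
    params = params or IsoDoseParams()
    return _hill1(_check_dose(dose), params.s_k_max, params.k_kacti)


def iso_taukr_factor(dose: float, params: IsoDoseParams | None = None) -> float:
    """Fractional increase of the I_Kr deactivation rate (dimensionless).

    The modified time constant is ``tau_Kr / (1 + iso_taukr_factor(dose))``;
    at the fitted maximum of 3.0 the deactivation rate is quadrupled.
    """
    params = params or IsoDoseParams()
    return _hill1(_check_dose(dose), params.dtau_kr_max, params.k_taukr)


def iso_fraction_ist(dose: float, params: IsoDoseParams | None = None) -> float:
    """Fractional increase of g_st (dimensionless)."""
    params = params or IsoDoseParams()
    return _hill1(_check_dose(dose), params.f_st_max, params.k_st)


def iso_apply(model, actions: IsoActionSet, params: IsoDoseParams | None = None):
    """Return a copy of `model` with the enabled ISO actions applied.

    Parameter semantics (only for enabled actions, and only at dose > 0):

    * ``g_CaL <- g_CaL * (1 + f_Ca)``
    * ``g_Kr <- g_Kr * (1 + f_K)`` and ``g_Ks <- g_Ks * (1 + f_K)``
    * ``g_st <- g_st * (1 + f_st)``
    * I_f activation half-voltage shifted by +S_f mV (via ``v_shift_f``)
    * I_Kr activation shifted by S_K mV (negative, via ``v_shift_kr``)
    * ``tau_Kr <- tau_Kr / (1 + d_tau)`` (via ``taukr_rate_scale``)
    * SR maximal release rate x ``sr_release_scale``; uptake x
      ``sr_uptake_scale`` (dose-independent once dose > 0)

    Raises ``UnsupportedActionError`` if an enabled action targets a
    parameter the model does not possess (e.g. I_st in the Kurata family).
    The input model is never mutated.
    """
    from .models.base import UnsupportedActionError  # avoid import cycle

    params = params or IsoDoseParams()
    dose = _check_dose(actions.dose)
    new = model.copy()
    if dose == 0.0:
        return new
    p = new.parameters

    def _require(name: str, action: str):
        if name not in p:
            raise UnsupportedActionError(
                f"ISO action {action!r} targets parameter {name!r}, which model "
                f"{model.name!r} does not have; disable the action flag"
            )

    if actions.enable_ical:
        _require("g_cal", "ical")
        p["g_cal"] *= 1.0 + iso_fraction_ical(dose, params)
    if actions.enable_gk:
        _require("g_kr", "gk")
        _require("g_ks", "gk")
        fk = iso_fraction_ik(dose, params)
        p["g_kr"] *= 1.0 + fk
        p["g_ks"] *= 1.0 + fk
    if actions.enable_ist:
        _require("g_st", "ist")
        p["g_st"] *= 1.0 + iso_fraction_ist(dose, params)
    if actions.enable_if:
        _require("v_shift_f", "if")
        p["v_shift_f"] += iso_shift_if(dose, params)
    if actions.enable_ikr_shift:
        _require("v_shift_kr", "ikr_shift")
        p["v_shift_kr"] += iso_shift_ikr_activation(dose, params)
    if actions.enable_taukr:
        _require("taukr_rate_scale", "taukr")
        p["taukr_rate_scale"] *= 1.0 + iso_taukr_factor(dose, params)
    if actions.enable_ca_handling:
        _require("p_rel", "ca_handling")
        _require("p_up", "ca_handling")
        p["p_rel"] *= params.sr_release_scale
        p["p_up"] *= params.sr_uptake_scale
        if "k_leak" in p:  # diastolic RyR leak belongs to the release machinery
            p["k_leak"] *= params.sr_release_scale
    return new
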