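"""Unit and property tests for the ISO concentration-response layer."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isosan.dose_response import (
    ACTION_NAMES,
    IsoActionSet,
    IsoDoseParams,
    iso_apply,
    iso_fraction_ical,
    iso_fraction_ik,
    iso_fraction_ist,
    iso_shift_if,
    iso_shift_ikr_activation,
    iso_taukr_factor,
)
from isosan.models import UnsupportedActionError, build_model

P = IsoDoseParams()

CURVES = [
    # (function, maximum, K_0.5)
    (iso_fraction_ical, P.f_ca_max, P.k_ca),
    (iso_shift_if, P.s_f_max, P.k_f),
    (iso_fraction_ik, P.f_k_max, P.k_gk),
    (iso_shift_ikr_activation, P.s_k_max, P.k_kacti),
    (iso_taukr_factor, P.dtau_kr_max, P.k_taukr),
    (iso_fraction_ist, P.f_st_max, P.k_st),
]


@pytest.mark.parametrize("fn,fmax,k", CURVES)
def test_zero_dose_is_exactly_zero(fn, fmax, k):
    assert fn(0.0) == 0.0


@pytest.mark.parametrize("fn,fmax,k", CURVES)
def test_half_maximum_at_k_half(fn, fmax, k):
    # Hill-1 curves hit fmax/2 at K exactly; the I_f curve to <=1e-12 rel
    assert fn(k) == pytest.approx(fmax / 2.0, rel=1e-12)


@pytest.mark.parametrize(
    "fn,dose,expected",
    [
        # direct scalar evaluations, frozen from an independent computation
        (iso_fraction_ical, 63.0, 0.486),
        (iso_shift_if, 50.0, 6.017984069042623),
        (iso_fraction_ik, 500.0, 1.8015414258188824),
        (iso_shift_ikr_activation, 50.0, -13.043478260869565),
        (iso_taukr_factor, 100.0, 2.4193548387096775),
        (iso_fraction_ist, 330.0, 0.9090909090909091),
    ],
)
def test_reference_evaluations(fn, dose, expected):
    assert fn(dose) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("fn,fmax,k", CURVES)
def test_saturation_at_high_dose(fn, fmax, k):
    # within 1% of the printed maximum far above K_0.5; the shallow I_f
    # curve (Hill n = 0.392) needs a correspondingly larger dose to reach
    # 99% of its asymptote
    mult = 1e6 if fn is iso_shift_if else 1e4
    assert fn(mult * k) == pytest.approx(fmax, rel=0.01)


@pytest.mark.parametrize("fn,fmax,k", CURVES)
@settings(deadline=None, max_examples=50, derandomize=True)
@given(d1=st.floats(0.0, 1e5), d2=st.floats(0.0, 1e5))
def test_monotone_in_dose(fn, fmax, k, d1, d2):
    lo, hi = sorted((d1, d2))
    a, b = fn(lo), fn(hi)
    assert abs(b) >= abs(a) - 1e-12
    assert abs(b) <= abs(fmax) + 1e-12


@pytest.mark.parametrize("fn,fmax,k", CURVES)
def test_negative_dose_rejected(fn, fmax, k):
    with pytest.raises(ValueError):
        fn(-1.0)


def test_params_validation():
    with pytest.raises(ValueError):
        IsoDoseParams(k_ca=0.0)
    with pytest.raises(ValueError):
        IsoDoseParams(n_f=-0.1)
    with pytest.raises(KeyError):
        IsoDoseParams.from_dict({"not_a_field": 1.0})
    d = IsoDoseParams().to_dict()
    assert IsoDoseParams.from_dict(d) == IsoDoseParams()


def test_action_set_helpers():
    a = IsoActionSet(dose=50.0)
    only = a.with_only("taukr")
    assert only.enabled("taukr")
    assert not any(only.enabled(x) for x in ACTION_NAMES if x != "taukr")
    without = a.without("gk")
    assert not without.enabled("gk")
    assert all(without.enabled(x) for x in ACTION_NAMES if x != "gk")
    with pytest.raises(ValueError):
        a.with_only("not_an_action")
    with pytest.raises(ValueError):
        IsoActionSet(dose=-5.0)


class TestIsoApply:
    def test_zero_dose_is_identity(self):
        m = build_model("boyett-central")
        out = iso_apply(m, IsoActionSet(dose=0.0))
        assert out.parameters == m.parameters
        np.testing.assert_array_equal(out.initial_state, m.initial_state)

    def test_input_model_untouched(self):
        m = build_model("boyett-central")
        before = dict(m.parameters)
        iso_apply(m, IsoActionSet(dose=500.0))
        assert m.parameters == before

    def test_gcal_scaling_matches_curve(self):
        # 50 nM: g_CaL x (1 + 0.54*50/57) = x1.4736842105263157
        m = build_model("boyett-central")
        out = iso_apply(m, IsoActionSet(dose=50.0))
        ratio = out.parameters["g_cal"] / m.parameters["g_cal"]
        assert ratio == pytest.approx(1.4736842105263157, rel=1e-12)

    def test_disabled_actions_leave_parameters_bit_identical(self):
        m = build_model("boyett-central")
        out = iso_apply(m, IsoActionSet(dose=50.0).with_only("taukr"))
        for name, val in m.parameters.items():
            if name == "taukr_rate_scale":
                assert out.parameters[name] == pytest.approx(
                    1.0 + iso_taukr_factor(50.0), rel=1e-12)
            else:
                assert out.parameters[name] == val

    def test_taukr_scaling_keeps_tau_positive(self):
        m = build_model("boyett-central")
        for dose in (1.0, 50.0, 1e4, 1e8):
            out = iso_apply(m, IsoActionSet(dose=dose))
            scale = out.parameters["taukr_rate_scale"]
            # tau' = tau/scale stays positive and shrinks at most 4-fold
            assert 1.0 < scale < 1.0 + P.dtau_kr_max + 1e-9

    def test_if_shift_is_depolarizing_and_kr_shift_negative(self):
        m = build_model("boyett-peripheral")
        out = iso_apply(m, IsoActionSet(dose=50.0))
        assert out.parameters["v_shift_f"] > 0
        assert out.parameters["v_shift_kr"] < 0

    def test_sr_flux_scaling(self):
        m = build_model("boyett-central")
        out = iso_apply(m, IsoActionSet(dose=50.0).with_only("ca_handling"))
        assert out.parameters["p_rel"] == pytest.approx(
            m.parameters["p_rel"] * 1.20)
        assert out.parameters["p_up"] == pytest.approx(
            m.parameters["p_up"] * 0.80)

    def test_ist_unsupported_on_kurata(self):
        m = build_model("kurata-central")
        with pytest.raises(UnsupportedActionError):
            iso_apply(m, IsoActionSet(dose=50.0))  # enable_ist defaults True
        # with the flag off, the same dose applies cleanly
        out = iso_apply(m, IsoActionSet(dose=50.0, enable_ist=False))
        assert out.parameters["g_cal"] > m.parameters["g_cal"]

    def test_composition_at_equal_total_effect(self):
        # iso_apply is a pure function: applying the same action set twice
        # from the same base gives bit-identical parameter tables
        m = build_model("boyett-central")
        a = iso_apply(m, IsoActionSet(dose=50.0))
        b = iso_apply(m, IsoActionSet(dose=50.0))
        assert a.parameters == b.parameters
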