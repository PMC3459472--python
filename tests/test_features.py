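"""AP detection and feature extraction on constructed waveforms."""

import numpy as np
import pytest

from isosan.engine import SimulationTrace
from isosan.features import (
    InsufficientBeatsError,
    compute_features,
    delta_features,
    detect_beats,
)

from conftest import make_synthetic_trace


def test_flat_trace_has_insufficient_beats():
    t = np.arange(0, 1000.0, 0.1)
    tr = SimulationTrace(time=t, vm=np.full_like(t, -60.0),
                         states=np.zeros((len(t), 1)), state_labels=("v",))
    with pytest.raises(InsufficientBeatsError):
        detect_beats(tr)


@pytest.mark.parametrize("period", [220.0, 300.0, 450.0])
def test_known_period_recovered(period):
    tr = make_synthetic_trace(period_ms=period, n_beats=6)
    feats = compute_features(tr)
    assert feats.cycle_length == pytest.approx(period, abs=tr.dt)
    assert feats.rate == pytest.approx(60000.0 / period, rel=1e-3)


def test_extremes_and_identities():
    tr = make_synthetic_trace(period_ms=300.0, mdp=-65.0, peak=20.0)
    f = compute_features(tr)
    assert f.mdp == pytest.approx(-65.0, abs=0.2)
    assert f.overshoot == pytest.approx(20.0, abs=0.2)
    # exact algebraic invariants of the feature set
    assert f.amplitude == f.overshoot - f.mdp
    assert f.rate == 60000.0 / f.cycle_length
    assert f.apd50 <= f.apd90 < f.cycle_length


def test_translation_invariance():
    a = compute_features(make_synthetic_trace(t_shift=0.0))
    b = compute_features(make_synthetic_trace(t_shift=137.0))
    assert a.cycle_length == pytest.approx(b.cycle_length, abs=a.cycle_length * 1e-3)
    assert a.mdp == pytest.approx(b.mdp, abs=0.3)
    assert a.apd90 == pytest.approx(b.apd90, abs=1.0)


def test_resampling_robustness():
    coarse = compute_features(make_synthetic_trace(dt=0.1))
    fine = compute_features(make_synthetic_trace(dt=0.05))
    assert fine.cycle_length == pytest.approx(coarse.cycle_length, rel=1e-3)
    assert fine.apd50 == pytest.approx(coarse.apd50, rel=1e-2)


def test_beat_count_consistent_with_span():
    tr = make_synthetic_trace(period_ms=300.0, n_beats=7)
    beats = detect_beats(tr)
    span = tr.time[-1] - tr.time[0]
    assert abs(len(beats) - span / 300.0) <= 1


class TestDeltaFeatures:
    def _feats(self, rate, mdp=-60.0):
        from isosan.features import APFeatureSet
        cl = 60000.0 / rate
        return APFeatureSet(cycle_length=cl, rate=rate, mdp=mdp,
                            overshoot=20.0, amplitude=20.0 - mdp,
                            apd50=80.0, apd90=110.0, dvdt_max=5.0,
                            cai_diastolic=None, cai_systolic=None,
                            n_beats_analyzed=5)

    def test_identical_inputs_give_zero_deltas(self):
        a = self._feats(180.0)
        d = delta_features(a, a)
        assert d["d_rate_pct"] == 0.0
        assert d["d_cl_pct"] == 0.0
        assert d["d_mdp_mv"] == 0.0

    def test_rate_arithmetic(self):
        d = delta_features(self._feats(150.0), self._feats(180.0))
        assert d["d_rate_pct"] == pytest.approx(20.0)

    def test_cycle_length_arithmetic(self):
        # CL 300 -> 240 ms is a 25% rate increase and a 20% CL decrease
        a, b = self._feats(200.0), self._feats(250.0)  # CL 300, 240
        d = delta_features(a, b)
        assert d["d_rate_pct"] == pytest.approx(25.0)
        assert d["d_cl_pct"] == pytest.approx(20.0)

    def test_rate_and_cl_deltas_algebraically_linked(self):
        a, b = self._feats(163.0), self._feats(201.0)
        d = delta_features(a, b)
        # dRate from rates equals dRate from cycle lengths
        from_cl = (a.cycle_length / b.cycle_length - 1.0) * 100.0
        assert d["d_rate_pct"] == pytest.approx(from_cl, abs=1e-12)
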