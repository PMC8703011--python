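"""Inhibition-factor law, conductance scaling and paced-model physiology."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cipasim import (
    CHANNELS,
    HillParams,
    NO_BLOCK_SENTINEL,
    PacingProtocol,
    inhibition_factor,
    scale_conductances,
    run_paced,
)
from cipasim import biomarkers as bm
from cipasim import cardiac_sim as cs
from conftest import single_channel_block


def _features(traces, bcl, control_auc=None):
    i = bm.select_ap(traces)
    b = traces[i]
    if control_auc is None:
        control_auc = (b.auc_inal, b.auc_ical)
    return bm.compute_features(b, control_auc, bcl)


class TestInhibitionFactor:
    @pytest.mark.parametrize("h", [0.5, 1.0, 2.0, 4.0])
    def test_half_block_at_ic50(self, h):
        assert inhibition_factor(100.0, HillParams(100.0, h)) == pytest.approx(0.5)

    def test_limits(self):
        assert inhibition_factor(0.0, HillParams(100.0, 1.0)) == 1.0
        assert inhibition_factor(1000.0, HillParams(100.0, 1.0)) == pytest.approx(1 / 11)
        assert inhibition_factor(1e6, NO_BLOCK_SENTINEL) == 1.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            inhibition_factor(-1.0, HillParams(100.0, 1.0))

    def test_strict_monotonicity_on_grid(self):
        d = np.linspace(1.0, 1e5, 1000)
        f = np.array([inhibition_factor(x, HillParams(500.0, 1.3)) for x in d])
        assert (np.diff(f) < 0).all()

    @given(
        ic50=st.floats(1.0, 1e6), h=st.floats(0.5, 4.0),
        d=st.floats(0.1, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_ic50_ordering(self, ic50, h, d):
        f = inhibition_factor(d, HillParams(ic50, h))
        assert 0.0 < f <= 1.0
        # larger IC50 (weaker drug) leaves more conductance
        f2 = inhibition_factor(d, HillParams(ic50 * 2.0, h))
        assert f2 >= f


class TestScaleConductances:
    def _sample(self, ikr_ic50=100.0):
        s = {c: NO_BLOCK_SENTINEL for c in CHANNELS}
        s["IKr"] = HillParams(ikr_ic50, 1.0)
        return s

    def test_no_drug_gives_unity(self, cell_config):
        v = scale_conductances(cell_config, self._sample(), 0.0)
        assert all(v.factors[c] == 1.0 for c in CHANNELS)

    def test_selective_block(self, cell_config):
        v = scale_conductances(cell_config, self._sample(100.0), 100.0)
        assert v.factors["IKr"] == pytest.approx(0.5)
        assert all(v.factors[c] == 1.0 for c in CHANNELS if c != "IKr")

    def test_monotone_over_concentration_sweep(self, cell_config):
        s = {c: HillParams(1000.0, 1.2) for c in CHANNELS}
        sweeps = [
            scale_conductances(cell_config, s, m * 250.0).factors
            for m in (1, 2, 3, 4)
        ]
        for c in CHANNELS:
            vals = [sw[c] for sw in sweeps]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_missing_channel_rejected(self, cell_config):
        with pytest.raises(ValueError):
            scale_conductances(cell_config, {"IKr": HillParams(1, 1)}, 10.0)
        with pytest.raises(ValueError):
            scale_conductances(cell_config, self._sample(), -5.0)


class TestPacedModel:
    def test_steady_state_cache_hit_is_identical(self, cell_config):
        a, amp_a = cs.steady_state_control(cell_config, PacingProtocol())
        b, amp_b = cs.steady_state_control(cell_config, PacingProtocol())
        assert amp_a == amp_b
        assert np.array_equal(a, b)

    def test_control_physiology(self, control_bundle):
        fv = control_bundle["features"]
        assert -90.0 <= fv.ap_resting <= -85.0
        assert 200.0 <= fv.apd90 <= 330.0
        assert fv.qinward == pytest.approx(1.0)
        assert 0.03 <= fv.qnet <= 0.08

    def test_already_at_steady_state(self, control_bundle):
        traces = control_bundle["traces"]
        bcl = control_bundle["protocol"].bcl
        first = _features([traces[0]], bcl).apd90
        last = _features([traces[-1]], bcl).apd90
        assert abs(first - last) < 1.0

    def test_record_last_count(self, control_bundle):
        proto = PacingProtocol(n_beats=6, record_last=3, stim_amplitude=control_bundle["amp"])
        traces = run_paced(control_bundle["config"], cs.NO_BLOCK, proto,
                           initial_state=control_bundle["state"],
                           stim_amplitude=control_bundle["amp"])
        assert len(traces) == 3
        assert traces[0].t[-1] == pytest.approx(proto.bcl)

    def test_determinism_bit_identical(self, control_bundle):
        proto = PacingProtocol(n_beats=3, record_last=1)
        kw = dict(initial_state=control_bundle["state"],
                  stim_amplitude=control_bundle["amp"])
        a = run_paced(control_bundle["config"], cs.NO_BLOCK, proto, **kw)
        b = run_paced(control_bundle["config"], cs.NO_BLOCK, proto, **kw)
        assert np.array_equal(a[0].vm, b[0].vm)
        assert np.array_equal(a[0].currents["IKr"], b[0].currents["IKr"])

    def test_step_halving_convergence(self, control_bundle):
        cfg = control_bundle["config"]
        proto = control_bundle["protocol"]
        kw = dict(initial_state=control_bundle["state"],
                  stim_amplitude=control_bundle["amp"])
        fine_cfg = dataclasses.replace(
            cfg, dt_min=cfg.dt_min / 2, dt_max=cfg.dt_max / 2,
            dv_max=cfg.dv_max / 2,
        )
        bcl = proto.bcl
        a = _features(run_paced(cfg, cs.NO_BLOCK, proto, **kw), bcl).apd90
        b = _features(run_paced(fine_cfg, cs.NO_BLOCK, proto, **kw), bcl).apd90
        assert abs(a - b) / a < 0.005

    def test_rest_stability_without_stimulus(self, control_bundle):
        proto = PacingProtocol(n_beats=1, record_last=1, bcl=1000.0,
                               stim_amplitude=0.0)
        tr = run_paced(control_bundle["config"], cs.NO_BLOCK, proto,
                       initial_state=control_bundle["state"],
                       stim_amplitude=0.0)[0]
        dvdt = np.gradient(tr.vm, tr.t)
        assert np.abs(dvdt).max() < 0.01

    def test_directional_pharmacology(self, control_bundle):
        cfg = control_bundle["config"]
        proto = control_bundle["protocol"]
        kw = dict(initial_state=control_bundle["state"],
                  stim_amplitude=control_bundle["amp"])
        bcl = proto.bcl
        ctrl = control_bundle["features"]
        cauc = control_bundle["control_auc"]
        ikr = _features(
            run_paced(cfg, single_channel_block("IKr", 0.3), proto, **kw),
            bcl, cauc,
        )
        ical = _features(
            run_paced(cfg, single_channel_block("ICaL", 0.3), proto, **kw),
            bcl, cauc,
        )
        assert ikr.apd90 > ctrl.apd90
        assert ical.apd90 < ctrl.apd90
        # qNet moves opposite ways under the two blocks
        assert ikr.qnet < ctrl.qnet < ical.qnet
        # inward-current block shows up in qInward
        assert ical.qinward < 0.8
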