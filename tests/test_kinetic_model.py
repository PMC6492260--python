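"""Kinetic model: phases, continuity, and analytic-vs-numeric derivatives."""

import numpy as np
import pytest

from asldesign import (
    AcquisitionConstants,
    InvalidParameterError,
    PhysioParams,
    apparent_t1,
    att_sensitivity,
    cbf_sensitivity_complete,
    cbf_sensitivity_simplified,
    gkm_signal,
)
from asldesign.kinetic_model import CBF_TO_RATE


class TestApparentT1:
    def test_zero_flow_equals_tissue_t1(self, acq):
        assert apparent_t1(0.0, acq) == pytest.approx(acq.t1_tissue)

    def test_nominal_outflow_value(self, acq):
        # 1 / (1/1.445 + (50/6000)/0.9)
        assert apparent_t1(50.0 / 6000.0, acq) == pytest.approx(1.42592, abs=1e-5)

    def test_monotone_decreasing_in_flow(self, acq):
        f = np.linspace(0.0, 0.03, 50)
        assert np.all(np.diff(apparent_t1(f, acq)) < 0)

    @pytest.mark.parametrize("bad", [-1e-3, np.nan, np.inf])
    def test_invalid_rate_rejected(self, acq, bad):
        with pytest.raises(InvalidParameterError):
            apparent_t1(bad, acq)


class TestSignal:
    def test_zero_before_arrival(self, acq):
        assert gkm_signal(0.3, PhysioParams(cbf=50, att=0.5), acq) == 0.0

    def test_peak_value_at_bolus_end(self, acq):
        # plateau value of the curve at t = tau + att for cbf=50, att=0.5:
        # 2 * (50/6000) * T1' * alpha * exp(-att/T1b) * (1 - exp(-tau/T1'))
        phys = PhysioParams(cbf=50, att=0.5)
        assert gkm_signal(1.9, phys, acq) == pytest.approx(9.3303e-3, rel=1e-4)

    def test_zero_perfusion_means_zero_signal(self, acq):
        t = np.linspace(0, 5, 100)
        assert np.all(gkm_signal(t, PhysioParams(cbf=0, att=0.7), acq) == 0)

    def test_linear_in_m0(self, phys_mid):
        a1 = AcquisitionConstants(m0_blood=1.0)
        a3 = AcquisitionConstants(m0_blood=3.0)
        t = np.linspace(0, 4, 50)
        np.testing.assert_allclose(
            3 * gkm_signal(t, phys_mid, a1), gkm_signal(t, phys_mid, a3)
        )

    def test_fixed_mode_linear_in_cbf(self, acq):
        t = np.linspace(0, 4, 50)
        s1 = gkm_signal(t, PhysioParams(cbf=20, att=0.9), acq, "fixed")
        s2 = gkm_signal(t, PhysioParams(cbf=60, att=0.9), acq, "fixed")
        np.testing.assert_allclose(3 * s1, s2, rtol=1e-12)

    @pytest.mark.parametrize("att", [0.3, 0.9, 1.6])
    @pytest.mark.parametrize("cbf", [10.0, 50.0, 90.0])
    def test_continuity_at_breakpoints(self, acq, cbf, att):
        eps = 1e-9
        phys = PhysioParams(cbf=cbf, att=att)
        tau = acq.label_duration
        for brk in (att, tau + att):
            lo = gkm_signal(brk - eps, phys, acq)
            hi = gkm_signal(brk + eps, phys, acq)
            assert abs(hi - lo) < 1e-10

    def test_peak_located_at_bolus_end(self, acq, phys_mid):
        t = np.linspace(0, 6, 6001)
        s = gkm_signal(t, phys_mid, acq)
        t_peak = t[np.argmax(s)]
        assert abs(t_peak - (acq.label_duration + phys_mid.att)) <= 6.0 / 6000 + 1e-12

    def test_negative_time_rejected(self, acq, phys_mid):
        with pytest.raises(InvalidParameterError):
            gkm_signal(-0.1, phys_mid, acq)


def _central_diff(fun, x, h):
    return (fun(x + h) - fun(x - h)) / (2 * h)


class TestSensitivities:
    """All analytic derivatives must agree with finite differences."""

    # breakpoint-avoiding sample times for att in (0.3, 1.6)
    TIMES = np.array([0.5, 1.1, 1.7, 2.3, 2.9, 3.5, 4.4])

    @pytest.mark.parametrize("seed", range(5))
    def test_simplified_matches_fd_of_fixed_model(self, acq, seed):
        r = np.random.default_rng(seed)
        cbf, att = r.uniform(10, 90), r.uniform(0.3, 1.6)
        h = 1e-7

        def model(f):
            return gkm_signal(self.TIMES, PhysioParams(cbf=f * 6000, att=att), acq, "fixed")

        fd = _central_diff(model, cbf * CBF_TO_RATE, h)
        an = cbf_sensitivity_simplified(self.TIMES, PhysioParams(cbf=cbf, att=att), acq)
        mask = np.abs(an) > 0
        assert np.max(np.abs((fd[mask] - an[mask]) / an[mask])) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_complete_matches_fd_of_exact_model(self, acq, seed):
        r = np.random.default_rng(100 + seed)
        cbf, att = r.uniform(10, 90), r.uniform(0.3, 1.6)
        f = cbf * CBF_TO_RATE
        h = f * 1e-5

        def model(fv):
            return gkm_signal(self.TIMES, PhysioParams(cbf=fv * 6000, att=att), acq, "self")

        fd = _central_diff(model, f, h)
        an = cbf_sensitivity_complete(self.TIMES, PhysioParams(cbf=cbf, att=att), acq)
        mask = np.abs(an) > 0
        assert np.max(np.abs((fd[mask] - an[mask]) / an[mask])) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_att_sensitivity_matches_fd(self, acq, seed):
        r = np.random.default_rng(200 + seed)
        cbf, att = r.uniform(10, 90), r.uniform(0.3, 1.6)
        h = 1e-7

        def model(a):
            return gkm_signal(self.TIMES, PhysioParams(cbf=cbf, att=a), acq, "fixed")

        fd = _central_diff(model, att, h)
        an = att_sensitivity(self.TIMES, PhysioParams(cbf=cbf, att=att), acq)
        mask = np.abs(an) > 1e-12
        assert np.max(np.abs((fd[mask] - an[mask]) / an[mask])) < 1e-5

    def test_zero_before_arrival(self, acq):
        phys = PhysioParams(cbf=50, att=1.0)
        assert cbf_sensitivity_simplified(0.5, phys, acq) == 0.0
        assert cbf_sensitivity_complete(0.5, phys, acq) == 0.0
        assert att_sensitivity(0.5, phys, acq) == 0.0

    def test_simplified_times_f_recovers_fixed_signal(self, acq):
        t = np.linspace(0.1, 4, 40)
        phys = PhysioParams(cbf=70, att=0.8)
        np.testing.assert_allclose(
            phys.f * np.asarray(cbf_sensitivity_simplified(t, phys, acq)),
            gkm_signal(t, phys, acq, "fixed"),
            rtol=1e-12,
        )

    def test_att_sensitivity_proportional_to_cbf(self, acq):
        t = np.linspace(0.1, 4, 40)
        s1 = att_sensitivity(t, PhysioParams(cbf=25, att=0.8), acq)
        s2 = att_sensitivity(t, PhysioParams(cbf=50, att=0.8), acq)
        np.testing.assert_allclose(2 * np.asarray(s1), s2, rtol=1e-12)

    def test_complete_equals_simplified_without_outflow(self):
        # with zero flow and T1' frozen at zero outflow the two agree exactly
        acq0 = AcquisitionConstants(fixed_outflow_cbf=0.0)
        t = np.linspace(0.1, 4, 40)
        phys = PhysioParams(cbf=0.0, att=0.8)
        np.testing.assert_allclose(
            cbf_sensitivity_complete(t, phys, acq0),
            cbf_sensitivity_simplified(t, phys, acq0),
            rtol=1e-12,
        )


class TestSignalProperties:
    """Model invariants over randomly drawn physiology."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        cbf=st.floats(1.0, 150.0),
        att=st.floats(0.1, 2.2),
        mode=st.sampled_from(["self", "fixed"]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_signal_nonnegative_continuous_and_peaked(self, cbf, att, mode):
        acq = AcquisitionConstants()
        phys = PhysioParams(cbf=cbf, att=att)
        t = np.linspace(0.0, att + acq.label_duration + 3.0, 800)
        s = np.asarray(gkm_signal(t, phys, acq, mode))
        assert np.all(s >= 0)
        # continuity at both breakpoints
        for brk in (att, acq.label_duration + att):
            lo = gkm_signal(max(brk - 1e-9, 0.0), phys, acq, mode)
            hi = gkm_signal(brk + 1e-9, phys, acq, mode)
            assert abs(hi - lo) < 1e-10
        # maximum sits at the end of the bolus
        step = t[1] - t[0]
        assert abs(t[np.argmax(s)] - (acq.label_duration + att)) <= step + 1e-12
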