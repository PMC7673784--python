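"""Channel kinetics, temperature correction, calcium, ribbon release and
receptor/phototransduction surrogates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retsbi import channels as ch


class TestEtaT:
    @pytest.mark.parametrize("q10,ts,te,expected", [
        (1.0, 30.0, 22.0, 1.0),
        (2.7, 25.0, 25.0, 1.0),
        (2.0, 32.0, 22.0, 2.0),
    ])
    def test_closed_form(self, q10, ts, te, expected):
        assert ch.eta_T(q10, ts, te) == pytest.approx(expected, rel=1e-12)

    def test_invalid_q10(self):
        with pytest.raises(ValueError):
            ch.eta_T(0.0, 30.0, 22.0)


class TestCalRates:
    def test_beta_at_minus_38(self):
        spec = ch.cal_gate_spec()
        _, b = ch.cal_rates(-38.0, spec, spec.t_eq)
        assert float(b) == pytest.approx(5.0, rel=1e-12)

    def test_alpha_removable_singularity(self):
        spec = ch.cal_gate_spec()
        a, _ = ch.cal_rates(-15.0, spec, spec.t_eq)
        assert float(a) == pytest.approx(1.0, rel=1e-9)
        # continuity across the pole
        a_near, _ = ch.cal_rates(-15.0 + 1e-7, spec, spec.t_eq)
        assert float(a_near) == pytest.approx(float(a), rel=1e-6)

    def test_dv_offset_shifts_curve(self):
        base = ch.cal_gate_spec()
        shifted = ch.cal_gate_spec(dv_alpha=5.0)
        vgrid = np.linspace(-80.0, 10.0, 41)
        a_sh, _ = ch.cal_rates(vgrid, shifted, base.t_eq)
        a_ba, _ = ch.cal_rates(vgrid - 5.0, base, base.t_eq)
        np.testing.assert_allclose(a_sh, a_ba, rtol=1e-12)

    def test_modifier_neutrality_bitwise(self):
        base = ch.cal_gate_spec()
        neutral = ch.cal_gate_spec(dv_alpha=0.0, dv_beta=0.0,
                                   tau_alpha=1.0, tau_beta=1.0)
        v = np.linspace(-90, 20, 45)
        ab = ch.cal_rates(v, base, 37.0)
        an = ch.cal_rates(v, neutral, 37.0)
        assert np.array_equal(ab[0], an[0]) and np.array_equal(ab[1], an[1])

    def test_tau_scales_rates(self):
        slow = ch.cal_gate_spec(tau_alpha=2.0)
        base = ch.cal_gate_spec()
        a_s, _ = ch.cal_rates(-30.0, slow, base.t_eq)
        a_b, _ = ch.cal_rates(-30.0, base, base.t_eq)
        assert float(a_s) == pytest.approx(float(a_b) / 2.0, rel=1e-12)


class TestConductance:
    def test_full_open(self):
        assert ch.channel_conductance(1.0, 2e-9, power=3) == pytest.approx(2e-9)

    def test_cube_law(self):
        assert ch.channel_conductance(0.5, 8e-9, power=3) == pytest.approx(1e-9)

    def test_markov_closed(self):
        occ = np.array([0.6, 0.4, 0.0, 0.0])
        assert ch.channel_conductance(occ, 1e-9, open_states=(3,)) == 0.0


class TestMarkov:
    def drive(self, inst, v_traj, dt_ms, t_sim=22.0):
        out = []
        for v in v_traj:
            inst.advance(float(v), 0.05, dt_ms, t_sim)
            out.append(inst.conductance())
        return np.array(out)

    def test_occupancy_conservation(self):
        spec = ch.hh_to_markov(ch.cal_gate_spec())
        inst = ch.ChannelInstance(comp=0, gmax=1e-9, v_rev=40.0, markov=spec)
        inst.init_state(-60.0, 22.0)
        rng = np.random.default_rng(0)
        v_traj = -60.0 + 40.0 * rng.standard_normal(200).cumsum() / 20.0
        for v in v_traj:
            inst.advance(float(np.clip(v, -100, 30)), 0.05, 0.1, 22.0)
            assert abs(inst.state.sum() - 1.0) < 1e-9

    def test_hh_markov_equivalence(self):
        """The CaL gate's mechanical 4-state expansion must reproduce the
        HH conductance trace (binomial occupancy is preserved exactly)."""
        hh_spec = ch.cal_gate_spec()
        hh = ch.ChannelInstance(comp=0, gmax=1e-9, v_rev=40.0, hh=hh_spec)
        ms = ch.ChannelInstance(comp=0, gmax=1e-9, v_rev=40.0,
                                markov=ch.hh_to_markov(hh_spec))
        hh.init_state(-60.0, 22.0)
        # binomial initial occupancy matching the HH state
        c0 = float(hh.state)
        k = np.arange(4)
        from math import comb
        ms.state = np.array([comb(3, int(i)) * c0 ** i * (1 - c0) ** (3 - i)
                             for i in k])
        t = np.linspace(0, 20, 400)
        v_traj = -45.0 + 20.0 * np.sin(2 * np.pi * t / 10.0)
        g_hh = self.drive(hh, v_traj, 0.05)
        g_ms = self.drive(ms, v_traj, 0.05)
        assert np.max(np.abs(g_hh - g_ms)) < 1e-6 * np.max(g_hh)

    def test_surrogate_flag(self):
        assert ch.hh_to_markov(ch.cal_gate_spec()).surrogate is True


class TestRibbon:
    def test_empty_pool_silent(self):
        syn = ch.RibbonSynapse(v_rrp_max=10.0, gl=5.0, v_rrp=0.0)
        assert ch.ribbon_release_rate(3.0, syn) == 0.0

    def test_unit_convention(self):
        syn = ch.RibbonSynapse(v_rrp_max=10.0, gl=1.0)
        assert ch.ribbon_release_rate(1.0, syn) == pytest.approx(1.0)

    def test_square_law(self):
        syn = ch.RibbonSynapse(v_rrp_max=10.0, gl=3.0)
        r1 = ch.ribbon_release_rate(1.5, syn)
        r2 = ch.ribbon_release_rate(3.0, syn)
        assert r2 == pytest.approx(4 * r1)

    def test_full_pool_unchanged_without_release(self):
        syn = ch.RibbonSynapse(v_rrp_max=10.0, rmsr=8.0)
        ch.rrp_update(syn, 0.0, 0.01)
        assert syn.v_rrp == 10.0

    def test_empty_pool_replenishes_at_rmsr(self):
        syn = ch.RibbonSynapse(v_rrp_max=10.0, rmsr=8.0, v_rrp=0.0)
        ch.rrp_update(syn, 0.0, 1.0)
        assert syn.v_rrp == pytest.approx(8.0)

    def test_long_run_mean_release_approaches_rmsr(self):
        """At saturating calcium the time-averaged release converges to the
        replenishment rate (steady-state balance)."""
        syn = ch.RibbonSynapse(v_rrp_max=10.0, gl=50.0, rmsr=8.0)
        dt = 1e-4
        released = 0.0
        T = 20.0
        n = int(T / dt)
        for _ in range(n):
            r = ch.ribbon_release_rate(5.0, syn)  # saturating
            released += r * dt
            ch.rrp_update(syn, r, dt)
        mean_rate = (released - syn.v_rrp_max + syn.v_rrp) / T
        assert mean_rate == pytest.approx(8.0, rel=0.02)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 20.0), min_size=5, max_size=60),
           st.floats(1e-4, 5e-3))
    def test_pool_bounds_never_violated(self, ca_trace, dt):
        syn = ch.RibbonSynapse(v_rrp_max=9.0, gl=80.0, rmsr=8.0)
        for ca in ca_trace:
            r = ch.ribbon_release_rate(ca, syn)
            ch.rrp_update(syn, r, dt)
            assert 0.0 <= syn.v_rrp <= syn.v_rrp_max


class TestCalcium:
    def test_rest_is_equilibrium(self):
        store = ch.CalciumStore()
        ch.calcium_update(store, 0.0, 1e-3)
        assert store.ca == pytest.approx(store.ca_rest, abs=1e-12)

    def test_pump_half_saturation(self):
        store = ch.CalciumStore(ca_pk=0.5, v_pump=60.0)
        assert store.pump_rate(0.5) == pytest.approx(30.0)

    def test_step_influx_then_relaxation(self):
        store = ch.CalciumStore(kappa_in=1e14, v_pump=60.0, tau_leak=0.2)
        dt = 1e-4
        for _ in range(5000):
            ch.calcium_update(store, 2e-12, dt)
        assert store.ca > store.ca_rest
        trace = []
        for _ in range(20000):
            ch.calcium_update(store, 0.0, dt)
            trace.append(store.ca)
        trace = np.array(trace)
        assert trace[-1] == pytest.approx(store.ca_rest, rel=0.01)
        assert np.all(np.diff(trace) <= 1e-12)  # monotone relaxation


class TestReceptor:
    def test_sign_conventions_at_zero_transmitter(self):
        glu = np.zeros(200)
        kai = ch.receptor_drive(glu, ch.PostsynapticReceptor(kind="kainate"),
                                dt=1e-3)
        mglur = ch.receptor_drive(glu, ch.PostsynapticReceptor(kind="mglur6"),
                                  dt=1e-3)
        assert np.all(kai == 0.0)
        assert np.all(mglur == 1.0)

    def test_tau_gamma_halflife(self):
        glu = np.zeros(4000)
        glu[:10] = 1000.0  # brief transmitter pulse, then decay
        dt = 1e-3
        half_lives = []
        for tau in (10.0, 20.0):
            rec = ch.PostsynapticReceptor(kind="kainate", tau_gamma=tau)
            out = ch.receptor_drive(glu, rec, dt)
            peak = out[9]
            below = np.argmax(out[9:] < peak / 2)
            half_lives.append(below * dt)
        assert half_lives[1] == pytest.approx(2 * half_lives[0], rel=0.05)

    def test_stc_equals_transmitter_scaling(self):
        glu = np.abs(np.sin(np.linspace(0, 3, 300))) * 40.0
        rec2 = ch.PostsynapticReceptor(kind="kainate", stc=2.0)
        rec1 = ch.PostsynapticReceptor(kind="kainate", stc=1.0)
        np.testing.assert_allclose(
            ch.receptor_drive(glu, rec2, 1e-3),
            ch.receptor_drive(2 * glu, rec1, 1e-3), rtol=1e-12)

    def test_open_fraction_bounded(self):
        glu = np.abs(np.random.default_rng(0).normal(0, 100, 500))
        out = ch.receptor_drive(glu, ch.PostsynapticReceptor(kind="kainate"),
                                1e-3)
        assert np.all((out >= 0) & (out <= 1))


class TestPhototransduction:
    def test_constant_rate_constant_current(self):
        spec = ch.PhototransductionSurrogate()
        out = ch.photocurrent(np.full(500, 1e4), spec, 1e-3)
        assert np.max(np.abs(out - out[0])) < 1e-18

    def test_monotone_in_rate(self):
        spec = ch.PhototransductionSurrogate()
        lo = ch.photocurrent(np.full(500, 1e4), spec, 1e-3)[-1]
        hi = ch.photocurrent(np.full(500, 3.1e4), spec, 1e-3)[-1]
        assert hi < lo < 0  # hyperpolarising, stronger at higher rate

    def test_step_transient_then_adapted_plateau(self):
        """Step from 10e3 to 31e3 P*/s: the current undershoots transiently
        and adapts back toward a plateau, matching the scalar ODE oracle."""
        spec = ch.PhototransductionSurrogate()
        dt = 1e-3
        rate = np.full(3000, 1e4)
        rate[1000:] = 3.1e4
        out = ch.photocurrent(rate, spec, dt)
        plateau = spec.steady_current(3.1e4)
        trough = out[1000:1100].min()
        assert trough < plateau  # transient overshoot of hyperpolarisation
        assert out[-1] == pytest.approx(plateau, rel=1e-3)
        # scalar ODE oracle: integrate the two-stage cascade directly
        y = ys = 1e4
        for k in range(1000, 3000):
            y = 3.1e4 + (y - 3.1e4) * math.exp(-dt * 1e3 / spec.tau_fast)
            ys = 3.1e4 + (ys - 3.1e4) * math.exp(-dt * 1e3 / spec.tau_slow)
        oracle = -spec.gain * y / (1.0 + spec.w_adapt * ys)
        assert out[-1] == pytest.approx(oracle, rel=1e-9)
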