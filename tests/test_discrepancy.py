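"""Fluorescence forward model, affine-invariant distance, bounded penalties
and peak-timing analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retsbi import discrepancy as dc


class TestKernel:
    def test_impulse_response_is_kernel(self):
        dt = 1e-3
        r = np.zeros(400)
        r[50] = 1.0
        out = dc.iglusnfr_from_release(r, dt)
        t_rel = (np.arange(400) - 50) * dt
        expected = np.where(t_rel >= 0, np.exp(-t_rel / 0.060), 0.0)
        expected[t_rel > 5 * 0.060] = 0.0  # truncated kernel
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_constant_rate_steady_value(self):
        dt = 1e-3
        out = dc.iglusnfr_from_release(np.full(2000, 3.0), dt)
        # geometric sum of the sampled, truncated kernel
        nk = int(round(5 * 0.060 / dt)) + 1
        expected = 3.0 * np.sum(np.exp(-np.arange(nk) * dt / 0.060))
        assert out[-1] == pytest.approx(expected, rel=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        r1, r2 = rng.uniform(0, 10, (2, 300))
        s = dc.iglusnfr_from_release(r1 + r2, 1e-3)
        s12 = dc.iglusnfr_from_release(r1, 1e-3) + \
            dc.iglusnfr_from_release(r2, 1e-3)
        np.testing.assert_allclose(s, s12, rtol=1e-12)


class TestDeltaIgluSnFR:
    def setup_method(self):
        self.target = np.sin(np.linspace(0, 12, 600)) + 0.3

    def test_identity_is_zero(self):
        assert dc.delta_iglusnfr(self.target, self.target) == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self):
        assert dc.delta_iglusnfr(self.target, 3.0 + 2.0 * self.target) \
            == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_is_one(self):
        assert dc.delta_iglusnfr(self.target, -self.target) == pytest.approx(1.0)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dc.delta_iglusnfr(np.ones(50), np.arange(50.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_by_one_under_nonneg_slope(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=120)
        s = rng.normal(size=120)
        d = dc.delta_iglusnfr(t, s)
        assert 0.0 <= d <= 1.0 + 1e-12


class TestBoundedPenalty:
    B = dc.PenaltyBounds(0.0, 50.0, 80.0, 100.0)

    @pytest.mark.parametrize("y", [50.0, 65.0, 80.0])
    def test_zero_inside_free_interval(self, y):
        assert dc.bounded_penalty(y, self.B) == 0.0

    def test_value_at_outer_bounds(self):
        expected = 1.0 - math.exp(-2.0)
        assert dc.bounded_penalty(0.0, self.B) == pytest.approx(-expected)
        assert dc.bounded_penalty(100.0, self.B) == pytest.approx(expected)

    def test_saturation_limits(self):
        assert dc.bounded_penalty(-1e9, self.B) == pytest.approx(-1.0)
        assert dc.bounded_penalty(1e9, self.B) == pytest.approx(1.0)

    def test_infinite_bounds_disable_branch(self):
        b = dc.PenaltyBounds(-100.0, -80.0, math.inf, math.inf)
        assert dc.bounded_penalty(1e6, b) == 0.0
        assert dc.bounded_penalty(-90.0, b) < 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(-500, 500))
    def test_continuity_and_monotonicity(self, y):
        b = self.B
        val = dc.bounded_penalty(y, b)
        assert -1.0 <= val <= 1.0
        # continuity at the free-interval edges
        eps = 1e-9
        assert abs(dc.bounded_penalty(b.tl - eps, b)) < 1e-12
        assert abs(dc.bounded_penalty(b.tu + eps, b)) < 1e-12
        # monotone in the distance to the nearest t-bound
        if y < b.tl:
            assert dc.bounded_penalty(y - 1.0, b) <= val
        elif y > b.tu:
            assert dc.bounded_penalty(y + 1.0, b) >= val

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            dc.PenaltyBounds(10.0, 0.0, 5.0, 20.0)


class TestResponseDeltas:
    def test_constant_at_rest(self):
        r = np.full(100, 4.0)
        v = np.full(100, -60.0)
        assert dc.response_deltas(r, v, 4.0, -60.0) == (0.0, 0.0)

    def test_max_absolute_excursion(self):
        v = np.full(200, -60.0)
        v[50] = -72.0
        v[100] = -53.0
        _, dv = dc.response_deltas(np.zeros(200), v, 0.0, -60.0)
        assert dv == pytest.approx(12.0)

    def test_release_transient(self):
        r = np.zeros(100)
        r[10] = 20.0
        dr, _ = dc.response_deltas(r, np.zeros(100), 0.0, 0.0)
        assert dr == pytest.approx(20.0)


class TestDiscrepancyVector:
    def make_traces(self):
        dt = 2e-3
        t = np.arange(0, 4, dt)
        rel = 2.0 + 7.0 * np.sin(2 * np.pi * 0.5 * t) ** 2
        fluor = dc.iglusnfr_from_release(rel, dt)
        v = -55.0 + 8.0 * np.sin(2 * np.pi * 0.5 * t) ** 2
        return fluor, rel, v

    def test_perfect_simulation_all_zero(self):
        fluor, rel, v = self.make_traces()
        target = 5.0 + 0.7 * fluor  # affine map of the simulation
        vec = dc.discrepancy_vector(target, fluor, rel, v,
                                    r_rest=rel[0], v_rest=v[0],
                                    bounds=dc.OFF_BC_BOUNDS)
        assert vec.total == pytest.approx(0.0, abs=1e-10)

    def test_cone_resting_rate_inside_band(self):
        assert dc.bounded_penalty(65.0, dc.CONE_BOUNDS["RateRest"]) == 0.0

    def test_bc_hyperpolarised_rest_penalty(self):
        # resting Vm of -70 mV against the BC band [tl=-65, pl=-80]
        expected = -1.0 + math.exp(-2.0 * 25.0 / 225.0)
        got = dc.bounded_penalty(-70.0, dc.OFF_BC_BOUNDS["VRest"])
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(-0.199, abs=5e-4)

    def test_off_on_band_asymmetry(self):
        # OFF tolerates resting release to 4 ves/s, ON only to 3;
        # OFF tolerates voltage swings to 25 mV, ON only to 15
        assert dc.bounded_penalty(3.5, dc.OFF_BC_BOUNDS["RateRest"]) == 0.0
        assert dc.bounded_penalty(3.5, dc.ON_BC_BOUNDS["RateRest"]) > 0.0
        assert dc.bounded_penalty(20.0, dc.OFF_BC_BOUNDS["VDelta"]) == 0.0
        assert dc.bounded_penalty(20.0, dc.ON_BC_BOUNDS["VDelta"]) > 0.0

    def test_total_is_l1_of_components(self):
        fluor, rel, v = self.make_traces()
        target = np.roll(fluor, 25)
        vec = dc.discrepancy_vector(target, fluor, rel, v - 20.0,
                                    r_rest=rel[0], v_rest=v[0] - 20.0,
                                    bounds=dc.ON_BC_BOUNDS)
        assert vec.total == pytest.approx(np.sum(np.abs(vec.as_array())))
        assert np.all(np.abs(vec.as_array()[1:]) <= 1.0)

    def test_missing_resting_state_rejected(self):
        fluor, rel, v = self.make_traces()
        with pytest.raises(ValueError, match="resting"):
            dc.discrepancy_vector(fluor, fluor, rel, v, r_rest=None,
                                  v_rest=None, bounds=dc.OFF_BC_BOUNDS)


class TestPeakTiming:
    def chirpy(self, n=4000, dt=2e-3):
        t = np.arange(n) * dt
        return t, np.sin(2 * np.pi * (0.5 * t + 0.15 * t ** 2))

    def test_identical_traces_zero_median(self):
        _, x = self.chirpy()
        diffs, med = dc.peak_time_differences(x, x, 2e-3)
        assert med == 0.0
        assert np.all(diffs == 0.0)

    def test_constant_delay_recovered(self):
        dt = 2e-3
        _, x = self.chirpy(dt=dt)
        delayed = np.roll(x, 8)  # 16 ms
        diffs, med = dc.peak_time_differences(x, delayed, dt,
                                              exclude=[(0.0, 0.1)])
        assert med == pytest.approx(16.0, abs=dt * 1e3)

    def test_exclusion_window_drops_everything(self):
        dt = 2e-3
        t = np.arange(2000) * dt
        x = np.sin(2 * np.pi * 1.0 * t)
        diffs, med = dc.peak_time_differences(x, x, dt,
                                              exclude=[(0.0, t[-1] + 1)])
        assert len(diffs) == 0
        assert math.isnan(med)
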