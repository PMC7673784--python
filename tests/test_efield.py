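"""Field solver vs closed forms, electrode RC inversion, lumped circuits and
tissue-parameter inference."""

import math
from dataclasses import replace

import numpy as np
import pytest

from retsbi import efield as ef
from retsbi.synth import make_synthetic_electrode_recordings


@pytest.fixture(scope="module")
def homogeneous_solution():
    """Large homogeneous domain approximating a half-space."""
    m = ef.RetinaFieldModel(sigma_retina=1.54, eps_retina=78.0,
                            radius=4e-3, h_bath=4e-3)
    return m, ef.solve_field(m, 1e-6, 0.0)


class TestSolver:
    def test_on_axis_matches_halfspace_closed_form(self, homogeneous_solution):
        m, sol = homogeneous_solution
        a = m.electrode_diameter / 2
        jperp = 1e-6 / (math.pi * a ** 2)
        for z in (10e-6, 30e-6, 60e-6, 100e-6):
            v_num = float(sol.potential(0.0, z))
            v_cf = ef.disk_halfspace_potential(z, a, jperp, 1.54)
            assert v_num == pytest.approx(v_cf, rel=0.02)

    def test_current_conservation(self, homogeneous_solution):
        _, sol = homogeneous_solution
        for z in (50e-6, 500e-6, 2e-3):
            assert sol.current_through_plane(z) == pytest.approx(1e-6,
                                                                 rel=0.005)

    def test_linearity_in_current(self):
        m = ef.RetinaFieldModel()
        s1 = ef.solve_field(m, 1e-6, 0.0)
        s2 = ef.solve_field(m, 2e-6, 0.0)
        r = np.array([0.0, 20e-6, 100e-6])
        z = np.array([10e-6, 40e-6, 90e-6])
        np.testing.assert_allclose(s2.potential(r, z),
                                   2.0 * s1.potential(r, z), rtol=1e-10)

    def test_grid_refinement_first_order(self):
        m = ef.RetinaFieldModel(sigma_retina=1.54, eps_retina=78.0,
                                radius=4e-3, h_bath=4e-3)
        a = 15e-6
        jperp = 1e-6 / (math.pi * a ** 2)
        zs = np.array([20e-6, 50e-6, 90e-6])
        errs = []
        for nr in (40, 80):
            sol = ef.solve_field(replace(m, grid_nr=nr), 1e-6, 0.0)
            v = np.array([float(sol.potential(0.0, z)) for z in zs])
            cf = ef.disk_halfspace_potential(zs, a, jperp, 1.54)
            errs.append(np.max(np.abs(v - cf) / cf))
        assert errs[0] / errs[1] >= 1.8

    def test_nonpositive_material_rejected(self):
        with pytest.raises(ValueError):
            ef.RetinaFieldModel(sigma_retina=0.0)


class TestSuperposition:
    def test_1x1_identical_to_single_disk(self):
        m = ef.RetinaFieldModel()
        single = ef.solve_field(m, 1e-6, 0.0)
        lay = ef.superpose_electrodes(m, "1x1", 1e-6)
        pts = np.array([[10e-6, 0.0, 30e-6], [50e-6, 20e-6, 60e-6]])
        np.testing.assert_allclose(lay.sample_xyz(pts),
                                   single.sample_xyz(pts), rtol=1e-12)

    def test_2x2_rotation_symmetry(self):
        m = ef.RetinaFieldModel()
        lay = ef.superpose_electrodes(m, "2x2", 1e-6)
        p = lay.sample_xyz(np.array([[40e-6, 10e-6, 25e-6]])).item()
        # rotate the sample point by 90 degrees about the array centre
        p_rot = lay.sample_xyz(np.array([[-10e-6, 40e-6, 25e-6]])).item()
        assert abs(p - p_rot) < 1e-9 * abs(p)

    def test_overlapping_disks_rejected(self):
        m = ef.RetinaFieldModel(electrode_pitch=20e-6)
        with pytest.raises(ValueError, match="overlap"):
            m.grid_layout("2x2")

    def test_against_coarse_3d_joint_solve(self):
        """Superposed 2x2 field vs a brute-force 3-D finite-volume solve of
        the joint boundary-value problem on a coarse Cartesian grid (graded
        laterally, disks treated as near-point sources)."""
        m = ef.RetinaFieldModel()
        lay = ef.superpose_electrodes(m, "2x2", 1e-6)

        import scipy.sparse as sp
        import scipy.sparse.linalg as spla

        h_ret = m.h_retina
        # lateral edges: 10 um cells over the central 0.24 mm, geometric to
        # +-2 mm; z edges: fine through the retina, geometric through 2 mm
        # of bath
        fine = np.arange(-0.12e-3, 0.12e-3 + 1e-9, 10e-6)
        grow = [fine[-1]]
        d = 10e-6
        while grow[-1] < 2e-3:
            d *= 1.45
            grow.append(min(grow[-1] + d, 2e-3))
        x_edges = np.concatenate([-np.array(grow[1:])[::-1], fine,
                                  np.array(grow[1:])])
        z_edges = np.concatenate([
            np.linspace(0.0, h_ret, 12),
            h_ret + np.geomspace(12e-6, 2e-3, 16)])
        xc = 0.5 * (x_edges[:-1] + x_edges[1:])
        zc = 0.5 * (z_edges[:-1] + z_edges[1:])
        dxs = np.diff(x_edges)
        dz = np.diff(z_edges)
        nx = ny = len(xc)
        nz = len(zc)
        sig = np.where(zc < h_ret, m.sigma_retina, m.sigma_ames)

        def idx(i, j, k):
            return (i * ny + j) * nz + k

        n_unk = nx * ny * nz
        rows, cols, vals = [], [], []
        diag = np.zeros(n_unk)
        rhs = np.zeros(n_unk)
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    p = idx(i, j, k)
                    if i + 1 < nx:
                        g = sig[k] * dxs[j] * dz[k] / (xc[i + 1] - xc[i])
                        q = idx(i + 1, j, k)
                        diag[p] += g; diag[q] += g
                        rows += [p, q]; cols += [q, p]; vals += [-g, -g]
                    if j + 1 < ny:
                        g = sig[k] * dxs[i] * dz[k] / (xc[j + 1] - xc[j])
                        q = idx(i, j + 1, k)
                        diag[p] += g; diag[q] += g
                        rows += [p, q]; cols += [q, p]; vals += [-g, -g]
                    if k + 1 < nz:
                        res = dz[k] / (2 * sig[k]) \
                            + dz[k + 1] / (2 * sig[k + 1])
                        g = dxs[i] * dxs[j] / res
                        q = idx(i, j, k + 1)
                        diag[p] += g; diag[q] += g
                        rows += [p, q]; cols += [q, p]; vals += [-g, -g]
                    if k == nz - 1:  # grounded top
                        diag[p] += dxs[i] * dxs[j] * sig[k] / (dz[k] / 2)
        # each disk's current enters the nearest bottom cell
        for (ex, ey) in lay.model.electrode_centers:
            i = int(np.argmin(np.abs(xc - ex)))
            j = int(np.argmin(np.abs(xc - ey)))
            rhs[idx(i, j, 0)] += 1e-6 / 4
        A = sp.csr_matrix((np.concatenate([vals, diag]),
                           (np.concatenate([rows, np.arange(n_unk)]),
                            np.concatenate([cols, np.arange(n_unk)]))),
                          shape=(n_unk, n_unk))
        v = spla.spsolve(A, rhs).reshape(nx, ny, nz)

        # compare away from the electrode plane, inside the fine region
        kz = int(np.searchsorted(zc, 45e-6))
        sel = np.abs(xc) <= 0.1e-3
        pts, vals3d = [], []
        for i in np.where(sel)[0][::2]:
            for j in np.where(sel)[0][::2]:
                pts.append([xc[i], xc[j], zc[kz]])
                vals3d.append(v[i, j, kz])
        pts = np.array(pts)
        vals3d = np.array(vals3d)
        v_sup = np.real(lay.sample_xyz(pts))
        rel = np.max(np.abs(v_sup - vals3d)) / np.max(np.abs(vals3d))
        assert rel < 0.05


class TestVexExtraction:
    def test_boundary_plane_near_zero(self, homogeneous_solution):
        _, sol = homogeneous_solution
        deep = abs(float(sol.potential(0.0, sol.model.h_retina
                                       + sol.model.h_bath - 1e-6)))
        near = abs(float(sol.potential(0.0, 20e-6)))
        assert deep < 1e-3 * near

    def test_symmetric_compartments_equal_vex(self, field_solution):
        centers = np.array([[30.0, 0.0, 30.0], [-30.0, 0.0, 30.0]])
        wave = np.ones(5) * 1e-6
        vex = ef.vex_at_compartments(field_solution, centers, wave,
                                     z_soma_um=30.0)
        np.testing.assert_allclose(vex[0], vex[1], rtol=1e-10)

    def test_monotone_decay_along_axis(self, field_solution):
        z = np.array([15.0, 30.0, 60.0, 90.0])
        centers = np.stack([np.zeros(4), np.zeros(4), z], axis=1)
        vex = ef.vex_at_compartments(field_solution, centers,
                                     np.ones(3) * 1e-6, z_soma_um=30.0,
                                     soma_index=1)
        mags = np.abs(vex[:, 0])
        assert np.all(np.diff(mags) < 0)

    def test_outside_domain_rejected(self, field_solution):
        centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 5000.0]])
        with pytest.raises(ValueError, match="compartment"):
            ef.vex_at_compartments(field_solution, centers, np.ones(3),
                                   z_soma_um=30.0)


class TestSinusoidAndRC:
    def test_exact_recovery(self):
        t = np.arange(0, 0.2, 1e-4)
        fit = ef.fit_sinusoid(2.5 * np.sin(2 * np.pi * 25 * t + 0.7), t, 25.0)
        assert fit.amplitude == pytest.approx(2.5, abs=1e-10)
        assert fit.phase == pytest.approx(0.7, abs=1e-10)

    def test_sin_convention_zero_phase(self):
        t = np.arange(0, 0.2, 1e-4)
        fit = ef.fit_sinusoid(np.sin(2 * np.pi * 25 * t), t, 25.0)
        assert fit.phase == pytest.approx(0.0, abs=1e-10)

    def test_noisy_amplitude_unbiased(self):
        t = np.arange(0, 0.4, 1e-4)
        rng = np.random.default_rng(0)
        amps = []
        for _ in range(50):
            x = 2.0 * np.sin(2 * np.pi * 25 * t + 0.3) \
                + rng.normal(0, 0.1, len(t))
            amps.append(ef.fit_sinusoid(x, t, 25.0).amplitude)
        assert np.mean(amps) == pytest.approx(2.0, rel=0.01)

    def test_too_short_trace_rejected(self):
        t = np.arange(0, 0.05, 1e-4)
        with pytest.raises(ValueError, match="periods"):
            ef.fit_sinusoid(np.sin(2 * np.pi * 25 * t), t, 25.0)

    @pytest.mark.parametrize("f", [25.0, 40.0])
    def test_rc_inversion_exact(self, f):
        R, C = 1e6, 1e-9
        z = ef.parallel_rc_impedance(R, C, f)
        i = ef.SinusoidFit(f, 1e-6, 0.3)
        v = ef.SinusoidFit(f, abs(z) * 1e-6, 0.3 + float(np.angle(z)))
        rc = ef.electrode_rc(v, i, f)
        assert rc.re == pytest.approx(R, rel=1e-9)
        assert rc.ce == pytest.approx(C, rel=1e-9)

    def test_zero_phase_means_pure_resistance(self):
        i = ef.SinusoidFit(25.0, 1e-6, 0.2)
        v = ef.SinusoidFit(25.0, 0.5, 0.2)
        rc = ef.electrode_rc(v, i, 25.0)
        assert rc.ce == 0.0
        assert rc.re == pytest.approx(0.5 / 1e-6)

    def test_zero_current_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ef.electrode_rc(ef.SinusoidFit(25.0, 1.0, 0.0),
                            ef.SinusoidFit(25.0, 0.0, 0.0), 25.0)


class TestCircuit:
    def test_homogeneity_limit(self):
        """With retina properties set to the bath's, the circuit current
        equals the no-retina circuit's current."""
        rc = ef.ElectrodeRC(25.0, 0.2, 3e5, 5e-9)
        v = ef.SinusoidFit(25.0, 0.2, 0.0)
        m = ef.RetinaFieldModel()
        hom = replace(m, sigma_retina=m.sigma_ames, eps_retina=m.eps_ames)
        bath_like = replace(m, sigma_retina=m.sigma_ames,
                            eps_retina=m.eps_ames, h_retina=m.h_retina)
        i1 = ef.simulate_circuit_current(v, rc, hom)
        i2 = ef.simulate_circuit_current(v, rc, bath_like)
        assert i1.amplitude == pytest.approx(i2.amplitude, rel=1e-12)

    def test_linearity_in_voltage(self):
        rc = ef.ElectrodeRC(25.0, 0.2, 3e5, 5e-9)
        m = ef.RetinaFieldModel()
        z = ef.tissue_impedance(m, 25.0)
        i1 = ef.simulate_circuit_current(ef.SinusoidFit(25.0, 0.2, 0.0), rc,
                                         m, z_tissue=z)
        i2 = ef.simulate_circuit_current(ef.SinusoidFit(25.0, 0.4, 0.0), rc,
                                         m, z_tissue=z)
        assert i2.amplitude == pytest.approx(2 * i1.amplitude, rel=1e-12)

    def test_forward_current_matches_lumped_hand_calc(self):
        """Independent complex-arithmetic hand calculation of the series
        electrode-RC + tissue circuit."""
        rc = ef.ElectrodeRC(40.0, 0.1, 2e5, 8e-9)
        m = ef.RetinaFieldModel(sigma_retina=0.05, eps_retina=5e6)
        z_t = ef.tissue_impedance(m, 40.0)
        v = ef.SinusoidFit(40.0, 0.1, 0.2)
        got = ef.simulate_circuit_current(v, rc, m, z_tissue=z_t)
        w = 2 * math.pi * 40.0
        z_el = rc.re / (1 + 1j * w * rc.re * rc.ce)
        i_hand = v.amplitude * np.exp(1j * v.phase) / (z_el + z_t)
        assert got.amplitude == pytest.approx(abs(i_hand), rel=1e-12)
        assert got.phase == pytest.approx(float(np.angle(i_hand)), abs=1e-12)

    def test_frequency_mismatch_rejected(self):
        rc = ef.ElectrodeRC(25.0, 0.2, 3e5, 5e-9)
        with pytest.raises(ValueError, match="frequency"):
            ef.simulate_circuit_current(ef.SinusoidFit(40.0, 0.2, 0.0), rc,
                                        ef.RetinaFieldModel())


class TestTissueInference:
    def test_discrepancy_orders_parameters(self):
        rec = make_synthetic_electrode_recordings(3e5, 5e-9, 0.076, 1.1e7,
                                                  seed=0)
        t = rec["t"]
        m = ef.RetinaFieldModel()
        targets = [ef.fit_sinusoid(tr, t, v.frequency)
                   for tr, v in zip(rec["i_retina"], rec["vstims"])]
        rcs = [ef.ElectrodeRC(v.frequency, v.amplitude, 3e5, 5e-9)
               for v in rec["vstims"]]

        def total(sigma, eps):
            mm = replace(m, sigma_retina=sigma, eps_retina=eps)
            out = 0.0
            for v, tg, rc in zip(rec["vstims"], targets, rcs):
                sim = ef.simulate_circuit_current(v, rc, mm)
                out += 0.5 * abs(sim.phasor - tg.phasor) ** 2
            return out

        d_true = total(0.076, 1.1e7)
        d_off = total(0.76, 1.1e7)
        assert d_true < d_off

    def test_degenerate_target_rejected(self):
        v = [ef.SinusoidFit(25.0, 0.2, 0.0), ef.SinusoidFit(40.0, 0.1, 0.0)]
        tg = [ef.SinusoidFit(25.0, 0.0, 0.0), ef.SinusoidFit(40.0, 1e-6, 0.0)]
        rcs = [ef.ElectrodeRC(25.0, 0.2, 3e5, 5e-9),
               ef.ElectrodeRC(40.0, 0.1, 3e5, 5e-9)]
        with pytest.raises(ValueError, match="degenerate"):
            ef.infer_tissue_params(v, tg, rcs, seed=0)

    def test_single_frequency_rejected(self):
        v = [ef.SinusoidFit(25.0, 0.2, 0.0), ef.SinusoidFit(25.0, 0.4, 0.0)]
        tg = [ef.SinusoidFit(25.0, 1e-6, 0.0)] * 2
        rcs = [ef.ElectrodeRC(25.0, 0.2, 3e5, 5e-9)] * 2
        with pytest.raises(ValueError, match="frequencies"):
            ef.infer_tissue_params(v, tg, rcs, seed=0)
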