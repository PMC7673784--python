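"""Quasi-static extracellular fields in a layered-cylinder retina/bath model,
electrode RC characterisation, and inference of tissue conductivity and
permittivity.

Geometry: the (photoreceptor-degenerated) retina is a cylinder of radius
2 mm and height 105 um sitting on the electrode plane; a bath cylinder
(Ames' medium, sigma = 1.54 S/m, relative permittivity 78) of height 2 mm
lies above it, its top face grounded (the return electrode).  Stimulation
electrodes are 30 um disks on the bottom face carrying a spatially uniform
normal current density ``j = istim / A_electrode``; all other boundaries are
insulating.

The potential solves ``div((sigma + i 2 pi f eps eps0) grad V) = 0``; at DC
the purely conductive problem.  The solver is a conservative finite-volume
discretisation on a graded axisymmetric (r, z) grid with the layer interface
aligned to a cell face, so the current through any horizontal plane is exact
up to the linear-solve residual.  Multi-electrode fields are superpositions
of laterally shifted single-disk solutions (exact for prescribed-current
electrodes up to the displaced outer-boundary approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from .sbi import TruncatedNormalPrior, run_inference, normalize_params, \
    denormalize_params

__all__ = [
    "EPS0",
    "RetinaFieldModel",
    "FieldSolution",
    "SinusoidFit",
    "ElectrodeRC",
    "solve_field",
    "superpose_electrodes",
    "vex_at_compartments",
    "fit_sinusoid",
    "electrode_rc",
    "parallel_rc_impedance",
    "tissue_impedance",
    "simulate_circuit_current",
    "infer_tissue_params",
    "disk_halfspace_potential",
]

EPS0 = 8.8541878128e-12  # F/m


@dataclass(frozen=True)
class RetinaFieldModel:
    """Cylinder geometry, material properties and electrode layout.

    Lengths in metres, conductivities in S/m, permittivities relative.
    ``electrode_centers`` are (x, y) positions on the bottom face.
    """

    sigma_retina: float = 0.076
    eps_retina: float = 1.1e7
    sigma_ames: float = 1.54
    eps_ames: float = 78.0
    radius: float = 2e-3
    h_retina: float = 105e-6
    h_bath: float = 2e-3
    electrode_diameter: float = 30e-6
    electrode_pitch: float = 70e-6
    electrode_centers: tuple = ((0.0, 0.0),)
    grid_nr: int = 80
    grid_nz: int = 96

    def __post_init__(self):
        if self.sigma_retina <= 0 or self.eps_retina <= 0:
            raise ValueError("conductivity and permittivity must be > 0")
        a = self.electrode_diameter / 2
        for (x, y) in self.electrode_centers:
            if math.hypot(x, y) + a > self.radius:
                raise ValueError("electrode outside the bottom face")

    def admittivity(self, f: float):
        """(kappa_retina, kappa_ames): sigma + i*2*pi*f*eps*eps0; real at DC."""
        if f == 0:
            return self.sigma_retina, self.sigma_ames
        w = 2 * math.pi * f
        return (self.sigma_retina + 1j * w * self.eps_retina * EPS0,
                self.sigma_ames + 1j * w * self.eps_ames * EPS0)

    def grid_layout(self, n_grid: str = "1x1") -> "RetinaFieldModel":
        """Model with an N x N electrode grid (e.g. '4x4') centred at the
        origin with the configured pitch."""
        n = int(n_grid.split("x")[0])
        offs = (np.arange(n) - (n - 1) / 2) * self.electrode_pitch
        centers = tuple((float(x), float(y)) for x in offs for y in offs)
        xs = [c[0] for c in centers]
        for i, a in enumerate(centers):
            for b in centers[i + 1:]:
                if math.hypot(a[0] - b[0], a[1] - b[1]) < self.electrode_diameter:
                    raise ValueError("overlapping electrode disks")
        return replace(self, electrode_centers=centers)


def _graded_edges(fine_to: float, total: float, d_fine: float,
                  growth: float = 1.15) -> np.ndarray:
    """Edge coordinates: uniform spacing d_fine up to ``fine_to``, then
    geometrically growing to ``total``."""
    edges = list(np.arange(0.0, fine_to + d_fine / 2, d_fine))
    d = d_fine
    while True:
        d *= growth
        nxt = edges[-1] + d
        if nxt >= total - 0.3 * d:
            edges.append(total)
            break
        edges.append(nxt)
    return np.asarray(edges)


def _insert_edge(edges: np.ndarray, value: float) -> np.ndarray:
    if np.any(np.isclose(edges, value, rtol=0, atol=1e-12)):
        i = int(np.argmin(np.abs(edges - value)))
        edges = edges.copy()
        edges[i] = value
        return edges
    return np.sort(np.append(edges, value))


@dataclass
class FieldSolution:
    """Interpolating sampler for one solved configuration.

    ``potential(r, z)`` returns the (complex at AC) potential in volts for
    the axisymmetric single-disk problem; ``sample_xyz(points)`` evaluates
    the multi-electrode superposition at Cartesian points (metres).
    """

    model: RetinaFieldModel
    istim: float
    frequency: float
    r_centers: np.ndarray
    z_centers: np.ndarray
    v_grid: np.ndarray          # (nr, nz)
    r_edges: np.ndarray
    z_edges: np.ndarray
    g_vert: np.ndarray          # vertical face conductances (nr, nz-1)
    v_electrode: complex        # area-mean surface potential on the disk
    per_electrode_current: float

    def __post_init__(self):
        real = np.isrealobj(self.v_grid)
        self._interp = RegularGridInterpolator(
            (self.r_centers, self.z_centers),
            self.v_grid if real else self.v_grid.real,
            bounds_error=False, fill_value=None)
        self._interp_imag = None if real else RegularGridInterpolator(
            (self.r_centers, self.z_centers), self.v_grid.imag,
            bounds_error=False, fill_value=None)

    def potential(self, r, z):
        shape = np.broadcast_shapes(np.shape(r), np.shape(z))
        pts = np.stack([np.broadcast_to(np.abs(r), shape).ravel(),
                        np.broadcast_to(z, shape).ravel()], axis=-1)
        out = self._interp(pts)
        if self._interp_imag is not None:
            out = out + 1j * self._interp_imag(pts)
        return out.reshape(shape)

    def sample_xyz(self, points: np.ndarray):
        """Superposed potential at Cartesian points (n, 3) in metres."""
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.zeros(len(pts), dtype=self.v_grid.dtype)
        for (ex, ey) in self.model.electrode_centers:
            r = np.hypot(pts[:, 0] - ex, pts[:, 1] - ey)
            out = out + self.potential(r, pts[:, 2])
        return out

    def current_through_plane(self, z: float):
        """Total vertical current (A) across the horizontal plane nearest to
        ``z`` (summed conservative face fluxes, times electrode count)."""
        j = int(np.argmin(np.abs(self.z_edges[1:-1] - z)))
        flux = np.sum(self.g_vert[:, j] * (self.v_grid[:, j] - self.v_grid[:, j + 1]))
        return flux * len(self.model.electrode_centers)


def solve_field(model: RetinaFieldModel, istim: float,
                frequency: float = 0.0) -> FieldSolution:
    """Solve the axisymmetric single-disk problem for the total stimulation
    current ``istim`` (A) shared uniformly by all electrodes of the layout
    (each disk carries ``istim / n_electrodes``); the returned sampler
    superposes the layout."""
    a = model.electrode_diameter / 2
    n_el = len(model.electrode_centers)
    i_disk = istim / n_el

    # fine spacing scales inversely with the requested resolution;
    # the defaults (grid_nr=80, grid_nz=96) give a/6 near the disk
    d_fine_r = a * 80.0 / (6.0 * max(model.grid_nr, 16))
    d_fine_z = a * 96.0 / (7.2 * max(model.grid_nz, 16))
    r_edges = _graded_edges(2 * a, model.radius, d_fine_r)
    z_total = model.h_retina + model.h_bath
    z_edges = _graded_edges(min(4 * a, model.h_retina), z_total, d_fine_z)
    z_edges = _insert_edge(z_edges, model.h_retina)
    nr, nz = len(r_edges) - 1, len(z_edges) - 1

    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    dr = np.diff(r_edges)
    dz = np.diff(z_edges)

    kap_ret, kap_ames = model.admittivity(frequency)
    kap_z = np.where(zc < model.h_retina, kap_ret, kap_ames)
    dtype = complex if frequency else float

    def idx(i, j):
        return i * nz + j

    n_unk = nr * nz
    rows, cols, vals = [], [], []
    diag = np.zeros(n_unk, dtype=dtype)
    rhs = np.zeros(n_unk, dtype=dtype)

    # radial faces
    ring_area = 2 * math.pi * r_edges[1:-1]  # per unit dz, at interior faces
    for i in range(nr - 1):
        for j in range(nz):
            g = ring_area[i] * dz[j] * kap_z[j] / (rc[i + 1] - rc[i])
            p, q = idx(i, j), idx(i + 1, j)
            diag[p] += g
            diag[q] += g
            rows += [p, q]
            cols += [q, p]
            vals += [-g, -g]

    # vertical faces (interior): harmonic mean across the layer interface
    face_area = math.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    g_vert = np.zeros((nr, nz - 1), dtype=dtype)
    for j in range(nz - 1):
        res = dz[j] / (2 * kap_z[j]) + dz[j + 1] / (2 * kap_z[j + 1])
        for i in range(nr):
            g = face_area[i] / res
            g_vert[i, j] = g
            p, q = idx(i, j), idx(i, j + 1)
            diag[p] += g
            diag[q] += g
            rows += [p, q]
            cols += [q, p]
            vals += [-g, -g]

    # top Dirichlet (grounded return electrode)
    for i in range(nr):
        g = face_area[i] * kap_z[-1] / (dz[-1] / 2)
        diag[idx(i, nz - 1)] += g

    # electrode disk source at the bottom face
    jperp = i_disk / (math.pi * a ** 2)
    src = np.zeros(nr)
    for i in range(nr):
        r0, r1 = r_edges[i], r_edges[i + 1]
        r1c = min(r1, a)
        if r1c > r0:
            src[i] = jperp * math.pi * (r1c ** 2 - r0 ** 2)
    for i in range(nr):
        if src[i]:
            rhs[idx(i, 0)] += src[i]

    A = sp.csr_matrix(
        (np.concatenate([np.asarray(vals, dtype=dtype),
                         diag]),
         (np.concatenate([rows, np.arange(n_unk)]),
          np.concatenate([cols, np.arange(n_unk)]))),
        shape=(n_unk, n_unk))
    v = spla.spsolve(A, rhs)
    resid = np.linalg.norm(A @ v - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8:
        raise RuntimeError(f"field solve did not converge (residual {resid:.2e})")
    v_grid = v.reshape(nr, nz)

    # surface potential on the disk: extrapolate through the half-cell
    mask = src > 0
    v_surf = v_grid[mask, 0] + jperp * (dz[0] / 2) / kap_z[0]
    w = src[mask]
    v_el = complex(np.sum(v_surf * w) / np.sum(w))

    return FieldSolution(model=model, istim=istim, frequency=frequency,
                         r_centers=rc, z_centers=zc, v_grid=v_grid,
                         r_edges=r_edges, z_edges=z_edges, g_vert=g_vert,
                         v_electrode=v_el, per_electrode_current=i_disk)


def superpose_electrodes(model: RetinaFieldModel, layout: str,
                         istim_total: float,
                         frequency: float = 0.0) -> FieldSolution:
    """Field of an N x N grid of disks (layout '1x1', '2x2', ...) carrying
    ``istim_total`` in total; each disk contributes a shifted copy of the
    single-disk solution with its area fraction of the current."""
    return solve_field(model.grid_layout(layout), istim_total, frequency)


def disk_halfspace_potential(z: np.ndarray, a: float, jperp: float,
                             sigma: float) -> np.ndarray:
    """Closed-form on-axis potential of a uniform-current-density disk on the
    insulating surface of a conductive half-space.

    Each surface point source spreads into a 2*pi solid angle
    (``V = I/(2 pi sigma R)``); integrating over the disk gives
    ``V(z) = (j / sigma) (sqrt(a^2 + z^2) - z)``.
    """
    z = np.asarray(z, float)
    return jperp / sigma * (np.sqrt(a ** 2 + z ** 2) - z)


def vex_at_compartments(sol: FieldSolution, centers_um: np.ndarray,
                        waveform: np.ndarray,
                        z_soma_um: float = 30.0,
                        soma_index: int = 0) -> np.ndarray:
    """Per-compartment extracellular voltage traces (V).

    ``centers_um`` are compartment centres (n, 3) in micrometres in the
    cell's own frame; the cell is placed with its soma at height
    ``z_soma_um`` above the electrode plane (dendrites facing the
    electrodes).  The solved field is linear in the stimulation current, so
    the time course is the spatial profile at the reference current scaled
    by ``waveform / istim_ref``.
    """
    c = np.atleast_2d(np.asarray(centers_um, float)) * 1e-6
    shift = np.array([0.0, 0.0, z_soma_um * 1e-6 - c[soma_index, 2]])
    pts = c + shift
    h_tot = sol.model.h_retina + sol.model.h_bath
    if np.any(pts[:, 2] < -1e-12) or np.any(pts[:, 2] > h_tot):
        bad = int(np.argmax((pts[:, 2] < -1e-12) | (pts[:, 2] > h_tot)))
        raise ValueError(f"compartment {bad} outside the retina cylinder")
    if np.any(np.hypot(pts[:, 0], pts[:, 1]) > sol.model.radius):
        bad = int(np.argmax(np.hypot(pts[:, 0], pts[:, 1]) > sol.model.radius))
        raise ValueError(f"compartment {bad} outside the retina cylinder")
    profile = np.real(sol.sample_xyz(pts))
    scale = np.asarray(waveform, float) / sol.istim
    return profile[:, None] * scale[None, :]


# ---------------------------------------------------------------------------
# Sinusoid fitting and the electrode RC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SinusoidFit:
    """``x(t) ~= A sin(2 pi f t + phi)``; amplitude >= 0, phase in (-pi, pi]."""

    frequency: float
    amplitude: float
    phase: float

    @property
    def phasor(self) -> complex:
        return self.amplitude * np.exp(1j * self.phase)

    def trace(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude * np.sin(2 * math.pi * self.frequency * t
                                       + self.phase)


@dataclass(frozen=True)
class ElectrodeRC:
    """Parallel RC model of the electrode (double layer plus parasitics) at
    one stimulus frequency and amplitude."""

    frequency: float
    amplitude: float
    re: float
    ce: float

    def __post_init__(self):
        if self.re <= 0 or self.ce < 0:
            raise ValueError("Re must be > 0 and Ce >= 0")

    def impedance(self) -> complex:
        return parallel_rc_impedance(self.re, self.ce, self.frequency)


def parallel_rc_impedance(r: float, c: float, f: float) -> complex:
    return r / (1.0 + 1j * 2 * math.pi * f * r * c)


def fit_sinusoid(trace: np.ndarray, t: np.ndarray, f: float) -> SinusoidFit:
    """Least-squares amplitude and phase at fixed frequency via quadrature
    projection over an integer number of periods."""
    x = np.asarray(trace, float)
    t = np.asarray(t, float)
    duration = t[-1] - t[0]
    if f * duration < 3:
        raise ValueError("trace must span at least 3 periods")
    # trim to an integer number of periods for unbiased projection
    n_per = math.floor(f * duration)
    keep = t - t[0] <= n_per / f + 1e-12
    x, t = x[keep], t[keep]
    w = 2 * math.pi * f
    s, cth = np.sin(w * t), np.cos(w * t)
    # solve the 2x2 normal equations (grids need not be uniform)
    m = np.array([[s @ s, s @ cth], [s @ cth, cth @ cth]])
    rhs = np.array([s @ x, cth @ x])
    cs, cc = np.linalg.solve(m, rhs)
    amp = math.hypot(cs, cc)
    phase = math.atan2(cc, cs)
    return SinusoidFit(frequency=f, amplitude=amp, phase=phase)


def electrode_rc(v_electrode: SinusoidFit, i_ames: SinusoidFit,
                 f: float) -> ElectrodeRC:
    """Invert the parallel-RC impedance from the voltage over and the current
    through the electrode:

    phiZ = phi(v) - phi(i);  |Z| = A(v)/A(i);
    Re = |Z| sqrt(1 + tan(phiZ)^2);  Ce = -tan(phiZ) / (2 pi f Re).
    """
    if i_ames.amplitude == 0:
        raise ValueError("current amplitude is zero")
    phi_z = v_electrode.phase - i_ames.phase
    phi_z = (phi_z + math.pi) % (2 * math.pi) - math.pi
    mag = v_electrode.amplitude / i_ames.amplitude
    re = mag * math.sqrt(1.0 + math.tan(phi_z) ** 2)
    ce = -math.tan(phi_z) / (2 * math.pi * f * re)
    return ElectrodeRC(frequency=f, amplitude=v_electrode.amplitude,
                       re=re, ce=max(ce, 0.0))


# ---------------------------------------------------------------------------
# Lumped circuit with the tissue block
# ---------------------------------------------------------------------------


def tissue_impedance(model: RetinaFieldModel, f: float,
                     i_ref: float = 1e-6) -> complex:
    """Terminal impedance of the cylinder model seen from the electrode to
    the grounded bath top: mean electrode surface potential per ampere."""
    sol = solve_field(model, i_ref, frequency=f)
    return sol.v_electrode / i_ref


def simulate_circuit_current(vstim: SinusoidFit, rc: ElectrodeRC,
                             model: RetinaFieldModel,
                             z_tissue: complex | None = None) -> SinusoidFit:
    """Current through the series combination of the RC electrode and the
    cylinder model's terminal impedance for a sinusoidal stimulus voltage."""
    if abs(rc.frequency - vstim.frequency) > 1e-9:
        raise ValueError("RC entry frequency does not match the stimulus")
    if z_tissue is None:
        z_tissue = tissue_impedance(model, vstim.frequency)
    i_ph = vstim.phasor / (rc.impedance() + z_tissue)
    return SinusoidFit(frequency=vstim.frequency,
                       amplitude=float(abs(i_ph)),
                       phase=float(np.angle(i_ph)))


def _current_mse(i_fit: SinusoidFit, i_target: SinusoidFit) -> float:
    """Mean squared error between two same-frequency sinusoids over a period
    (closed form): 0.5 |phasor difference|^2."""
    return 0.5 * abs(i_fit.phasor - i_target.phasor) ** 2


def infer_tissue_params(vstims: Sequence[SinusoidFit],
                        targets: Sequence[SinusoidFit],
                        rcs: Sequence[ElectrodeRC],
                        seed: int,
                        model: RetinaFieldModel | None = None,
                        rounds: int = 3, n_per_round: int = 50) -> tuple:
    """Two-stage inference of (sigma_retina, eps_retina).

    Stage 1 samples the exponents of ``sigma = 2**p_sigma * 0.1 S/m`` and
    ``eps = 2**p_eps * 1e6`` with Gaussian priors (mean 1.0, sd 2.0).
    Stage 2 re-runs the inference with truncated-normal priors over the box
    spanned by the best 10% of stage-1 samples, in normalised [0,1] space
    with diagonal std 0.3.  The discrepancy per stimulus is the period-mean
    squared error between target and simulated currents, summed over
    stimuli.  Returns ``(sigma, eps, audit)`` for the lowest-discrepancy
    sample seen in either stage.
    """
    if model is None:
        model = RetinaFieldModel()
    freqs = sorted({v.frequency for v in vstims})
    if len(vstims) < 2 or len(freqs) < 2:
        raise ValueError("need >= 2 stimuli spanning >= 2 frequencies")
    for tg in targets:
        if tg.amplitude == 0:
            raise ValueError("degenerate target current (zero amplitude)")

    def discrepancy(sigma: float, eps: float) -> float:
        m = replace(model, sigma_retina=sigma, eps_retina=eps)
        z_by_f = {f: tissue_impedance(m, f) for f in freqs}
        tot = 0.0
        for v, tg, rc in zip(vstims, targets, rcs):
            sim = simulate_circuit_current(v, rc, m,
                                           z_tissue=z_by_f[v.frequency])
            tot += _current_mse(sim, tg)
        return tot

    all_samples = []  # (delta, sigma, eps)

    def make_simulator(to_phys):
        def simulator(theta, sim_seed):
            sigma, eps = to_phys(theta)
            if sigma <= 0 or eps <= 0:
                return "invalid", np.array([np.inf])
            d = discrepancy(sigma, eps)
            all_samples.append((d, sigma, eps))
            return "ok", np.array([d])
        return simulator

    # stage 1: log space
    prior1 = TruncatedNormalPrior(mean=[1.0, 1.0], std=[2.0, 2.0],
                                  box=[[-11.0, 13.0], [-11.0, 13.0]])
    sim1 = make_simulator(lambda p: (2.0 ** p[0] * 0.1, 2.0 ** p[1] * 1e6))
    run_inference(sim1, prior1, rounds=rounds, n_per_round=n_per_round,
                  seed=seed, hidden=(20, 20), epochs=500)

    stage1 = sorted(all_samples)[: max(1, len(all_samples) // 10)]
    sig_v = np.array([s[1] for s in stage1])
    eps_v = np.array([s[2] for s in stage1])
    bounds = np.array([[sig_v.min(), sig_v.max()],
                       [eps_v.min(), eps_v.max()]])
    if bounds[0, 0] == bounds[0, 1]:
        bounds[0] += [-1e-6, 1e-6]
    if bounds[1, 0] == bounds[1, 1]:
        bounds[1] += [-1.0, 1.0]
    mu = normalize_params(np.array([sig_v.mean(), eps_v.mean()]), bounds)

    # stage 2: linear space around the best decade, normalised to [0, 1]
    prior2 = TruncatedNormalPrior(mean=mu, std=[0.3, 0.3],
                                  box=[[0.0, 1.0], [0.0, 1.0]])
    sim2 = make_simulator(lambda u: tuple(denormalize_params(u, bounds)))
    run_inference(sim2, prior2, rounds=rounds, n_per_round=n_per_round,
                  seed=seed + 1, hidden=(20, 20), epochs=500)

    best = min(all_samples)
    audit = {"n_evaluations": len(all_samples),
             "best_discrepancy": best[0],
             "stage2_bounds": bounds}
    return best[1], best[2], audit
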