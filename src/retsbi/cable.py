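"""Compartmental membrane-equation integrator.

The voltage of compartment ``n`` coupled to its neighbours follows

    cm_n dVm_n/dt = sum_k (Vm_k - Vm_n)/(ri_k + ri_n)
                    + (Vr_n + Vex_n - Vm_n)/rm_n
                    + sum_e g_e (Ve + Vex_n - Vm_n)
                    + I_inj,n
    (+ cm_n dVex_n/dt)

with ``Vex`` an optional per-compartment extracellular potential.
Internally the state variable is the transmembrane potential
``U = Vm - Vex``; in these terms the extracellular forcing enters only
through the axial differences ``Vex_k - Vex_n``, which makes the invariance
of ``U`` under spatially uniform ``Vex`` exact.  The reported ``Vm`` is
``U + Vex``.

Integration: for a passive cell (no gated channels) the system is linear
with piecewise-constant input, and each step applies a cached matrix
exponential propagator — machine precision independent of dt.  With active
channels, gating states advance by exact exponential (or Markov matrix-
exponential) sub-steps and the voltages by Crank-Nicolson with conductances
frozen over the step.

Units: volts, seconds, siemens, farads, amperes internally; the public
surface speaks mV where noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg
from scipy.linalg.lapack import dgesv as _dgesv

from .channels import (CalciumStore, ChannelInstance, RibbonSynapse,
                       ribbon_release_rate, rrp_update, calcium_update)
from .morphology import Compartment

__all__ = ["CellModel", "SimulationResult", "simulate", "apply_vex",
           "voltage_clamp_screen"]


@dataclass
class SynapticInput:
    """Conductance-based synaptic drive onto a compartment: the open-fraction
    trace (from :func:`channels.receptor_drive`) scaled by ``g_syn`` (S)
    toward reversal ``v_rev`` (mV)."""

    comp: int
    g_syn: float
    v_rev: float
    open_fraction: np.ndarray


@dataclass
class CellModel:
    """Compartments plus membrane machinery; the simulator's state owner.

    ``compartments`` must carry passive constants (see
    :func:`morphology.compartmentalize`).  ``channels`` / ``synapses`` /
    ``calcium_stores`` attach to compartments by index.  ``soma`` marks the
    compartment used by the voltage-clamp screen.
    """

    compartments: list[Compartment]
    vr: float = -60.0  # mV
    t_sim: float = 37.0  # degC
    channels: list[ChannelInstance] = field(default_factory=list)
    synapses: list[RibbonSynapse] = field(default_factory=list)
    calcium_stores: list[CalciumStore] = field(default_factory=list)
    synaptic_inputs: list[SynapticInput] = field(default_factory=list)
    vex: np.ndarray | None = None  # (n_comp, n_t) volts
    soma: int = 0
    light_collecting_area_um2: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.compartments)
        if not 20.0 <= self.t_sim <= 40.0:
            raise ValueError("t_sim must be within [20, 40] degC")
        for ch in self.channels:
            if not 0 <= ch.comp < n:
                raise ValueError(f"channel references missing compartment {ch.comp}")
        for syn in self.synapses:
            if not 0 <= syn.comp < n:
                raise ValueError(f"synapse references missing compartment {syn.comp}")
        for st in self.calcium_stores:
            if not 0 <= st.comp < n:
                raise ValueError(f"calcium store references missing compartment {st.comp}")
        # ca_source channels must have a matching store
        self._store_by_comp = {st.comp: st for st in self.calcium_stores}

    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    def is_passive(self) -> bool:
        return not self.channels and not self.synaptic_inputs

    def axial_laplacian(self) -> np.ndarray:
        """Dense graph Laplacian-like coupling matrix L (S): row n holds
        ``sum_k (V_k - V_n) g_nk`` with ``g_nk = 1/(ri_k + ri_n)``."""
        n = self.n_comp
        L = np.zeros((n, n))
        for c in self.compartments:
            for k in c.neighbors:
                if k <= c.id:
                    continue
                other = self.compartments[k]
                g = 1.0 / (c.ri + other.ri)
                L[c.id, c.id] -= g
                L[c.id, k] += g
                L[k, k] -= g
                L[k, c.id] += g
        return L


@dataclass
class SimulationResult:
    """Shared-grid traces: ``t`` (s), ``vm`` (n_comp, n_t) mV, per-synapse
    release rates (ves/s), per-store [Ca]0 (uM) and a status flag."""

    t: np.ndarray
    vm: np.ndarray
    release: np.ndarray
    ca: np.ndarray
    status: str = "ok"
    pool: np.ndarray | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def mean_release(self) -> np.ndarray:
        """Mean release-rate trace over all synapses (ves/s)."""
        if self.release.size == 0:
            raise ValueError("cell has no synapses")
        return self.release.mean(axis=0)


def apply_vex(cell: CellModel, vex: np.ndarray) -> CellModel:
    """Attach per-compartment extracellular voltage traces (V).

    ``vex`` has shape (n_comp, n_t) on the simulation grid.  Without
    attachment ``Vex == 0``.
    """
    vex = np.asarray(vex, dtype=float)
    if vex.ndim != 2 or vex.shape[0] != cell.n_comp:
        raise ValueError(
            f"vex must be (n_comp={cell.n_comp}, n_t); got {vex.shape}")
    cell.vex = vex
    return cell


def _fast_eligible(cell: CellModel, clamp) -> bool:
    """Compiled-kernel envelope: HH channels with form-coded rates, at most
    one calcium store per compartment, no clamp, an active (non-passive)
    model."""
    if clamp is not None or cell.is_passive():
        return False
    for chn in cell.channels:
        if chn.hh is None:
            return False
        if not hasattr(chn.hh.alpha, "form") or not hasattr(chn.hh.beta, "form"):
            return False
    comps_with_store = [st.comp for st in cell.calcium_stores]
    if len(set(comps_with_store)) != len(comps_with_store):
        return False
    return True


def simulate(cell: CellModel, dt: float, t_total: float,
             i_inj: np.ndarray | Callable[[float], np.ndarray] | None = None,
             v0: np.ndarray | float | None = None,
             settle: float = 0.0,
             clamp: tuple[int, float, float, float] | None = None,
             record_pool: bool = False,
             engine: str = "auto") -> SimulationResult:
    """Integrate the cell for ``t_total`` seconds at step ``dt``.

    Parameters
    ----------
    i_inj:
        Injected current per compartment: array (n_comp, n_t) in amperes, or
        a callable ``t -> (n_comp,)``, or None.
    v0:
        Initial transmembrane potential (mV); default Vr.
    settle:
        Pre-roll duration (s) integrated before t=0 under the t=0 input to
        relax the model to its background state (not recorded).
    clamp:
        ``(comp, v_clamp_mV, t_on, t_off)`` — hold one compartment at a fixed
        voltage during [t_on, t_off).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = cell.n_comp
    nt = int(round(t_total / dt)) + 1
    t = np.arange(nt) * dt

    if callable(i_inj):
        inj = np.stack([np.asarray(i_inj(tk), dtype=float) for tk in t], axis=1)
    elif i_inj is None:
        inj = np.zeros((n, nt))
    else:
        inj = np.asarray(i_inj, dtype=float)
        if inj.shape != (n, nt):
            raise ValueError(f"i_inj shape {inj.shape} != {(n, nt)}")

    vex = cell.vex
    if vex is not None and vex.shape[1] != nt:
        raise ValueError(f"vex has {vex.shape[1]} samples, grid needs {nt}")
    for s in cell.synaptic_inputs:
        if len(s.open_fraction) != nt:
            raise ValueError("synaptic input trace length mismatch")

    if v0 is None:
        u = np.full(n, cell.vr * 1e-3)
    else:
        u = np.full(n, 1e-3) * np.asarray(v0, dtype=float)

    # initialise gating states, calcium, pools at the initial voltage
    for ch in cell.channels:
        if ch.state is None:
            ch.init_state(u[ch.comp] * 1e3, cell.t_sim)
    store_by_comp = cell._store_by_comp

    vm_out = np.empty((n, nt))
    rel_out = np.empty((len(cell.synapses), nt))
    ca_out = np.empty((len(cell.calcium_stores), nt))
    pool_out = np.empty((len(cell.synapses), nt)) if record_pool else None

    cm = np.array([c.cm for c in cell.compartments])
    gm = np.array([1.0 / c.rm for c in cell.compartments])
    L = cell.axial_laplacian()
    passive = cell.is_passive()
    eye = np.eye(n)
    # constant parts of the Crank-Nicolson step
    M0 = eye - 0.5 * dt * L / cm[:, None]
    diag_idx = np.arange(n)
    vr_v = cell.vr * 1e-3

    # cached propagator for the passive linear path (A is then constant)
    prop = None

    n_settle = int(round(settle / dt))
    dt_ms = dt * 1e3

    if vex is not None:
        # per-step axial current injected by extracellular gradients:
        # row n of L applied to the Vex column
        vex_axial = L @ vex
    else:
        vex_axial = None

    if engine not in ("auto", "numpy", "fast"):
        raise ValueError("engine must be 'auto', 'numpy' or 'fast'")
    use_fast = engine in ("auto", "fast") and _fast_eligible(cell, clamp)
    if engine == "fast" and not use_fast:
        raise ValueError("cell is outside the compiled-kernel envelope")
    if use_fast:
        from . import _fastpath as fp

        if fp.HAVE_NUMBA:
            status = _run_fast(cell, u, L, M0, gm, cm, vr_v, dt, n_settle,
                               nt, inj, vex_axial, vm_out, rel_out, ca_out,
                               pool_out, record_pool)
            if vex is not None and status == "ok":
                vm_out += vex * 1e3
            return SimulationResult(t=t, vm=vm_out, release=rel_out,
                                    ca=ca_out, status=status,
                                    pool=pool_out)

    status = "ok"
    for step in range(-n_settle, nt):
        k = max(step, 0)
        v_mv = u * 1e3

        # --- record ---
        if step >= 0:
            vm_out[:, step] = v_mv + (vex[:, step] * 1e3 if vex is not None else 0.0)
            for si, st in enumerate(cell.calcium_stores):
                ca_out[si, step] = st.ca
            for si, syn in enumerate(cell.synapses):
                st = store_by_comp.get(syn.comp)
                ca = st.ca if st is not None else 0.0
                rel_out[si, step] = ribbon_release_rate(ca, syn)
                if record_pool:
                    pool_out[si, step] = syn.v_rrp
        if step == nt - 1:
            break

        # --- channel conductances frozen at current state ---
        g_extra = np.zeros(n)
        b_extra = inj[:, k].copy()
        ca_current = np.zeros(n)
        for ch in cell.channels:
            g = ch.conductance()
            g_extra[ch.comp] += g
            b_extra[ch.comp] += g * ch.v_rev * 1e-3
            if ch.ca_source:
                ca_current[ch.comp] += g * (u[ch.comp] - ch.v_rev * 1e-3)
        for s in cell.synaptic_inputs:
            g = s.g_syn * s.open_fraction[k]
            g_extra[s.comp] += g
            b_extra[s.comp] += g * s.v_rev * 1e-3
        if vex_axial is not None:
            b_extra = b_extra + vex_axial[:, k]

        gt = gm + g_extra
        b = (gm * vr_v + b_extra) / cm

        clamped = None
        if clamp is not None:
            ci, vc, t_on, t_off = clamp
            t_now = step * dt
            if t_on <= t_now < t_off:
                clamped = (ci, vc * 1e-3)

        if passive and clamped is None:
            if prop is None:
                A = (L - np.diag(gt)) / cm[:, None]
                # block form handles singular A (e.g. leakless cables):
                # expm([[A, I], [0, 0]] dt) = [[P, Q], [0, I]],
                # Q = int_0^dt exp(A s) ds
                blk = np.zeros((2 * n, 2 * n))
                blk[:n, :n] = A * dt
                blk[:n, n:] = eye * dt
                E = scipy.linalg.expm(blk)
                prop = (E[:n, :n], E[:n, n:])
            P, Aint = prop
            u = P @ u + Aint @ b
        else:
            if clamped is not None:
                ci, vc = clamped
                u[ci] = vc
            # Crank-Nicolson with conductances frozen over the step:
            # M = I - dt/2 (L - diag(gt))/cm differs from the precomputed M0
            # only on the diagonal
            half = 0.5 * dt * gt / cm
            rhs = u + 0.5 * dt * (L @ u - gt * u) / cm + dt * b
            M = M0.copy()
            M[diag_idx, diag_idx] += half
            if clamped is not None:
                ci, vc = clamped
                M[ci, :] = 0.0
                M[ci, ci] = 1.0
                rhs[ci] = vc
            _, _, u, info = _dgesv(M, rhs, overwrite_a=True)
            if info != 0:
                status = "unstable"
                vm_out[:, max(step, 0):] = np.nan
                break
            if clamped is not None:
                u[clamped[0]] = clamped[1]

        # instability screen (checked periodically to keep the loop lean)
        if step % 16 == 0 or step == nt - 2:
            if not np.all(np.isfinite(u)) or np.any(np.abs(u) > 1.0):
                status = "unstable"
                vm_out[:, max(step, 0):] = np.nan
                break

        # --- advance gating states, calcium, pools ---
        v_new_mv = u * 1e3
        for ch in cell.channels:
            st = store_by_comp.get(ch.comp)
            ca = st.ca if st is not None else 0.05
            ch.advance(v_new_mv[ch.comp], ca, dt_ms, cell.t_sim)
        for st in cell.calcium_stores:
            calcium_update(st, ca_current[st.comp], dt)
        for syn in cell.synapses:
            st = store_by_comp.get(syn.comp)
            ca = st.ca if st is not None else 0.0
            r = ribbon_release_rate(ca, syn)
            rrp_update(syn, r, dt)

    return SimulationResult(t=t, vm=vm_out, release=rel_out, ca=ca_out,
                            status=status, pool=pool_out)


def _run_fast(cell: CellModel, u, L, M0, gm, cm, vr_v, dt, n_settle, nt,
              inj, vex_axial, vm_out, rel_out, ca_out, pool_out,
              record_pool) -> str:
    """Pack the cell into flat arrays, run the compiled kernel and write the
    evolved channel/calcium/pool states back onto the python objects."""
    from ._fastpath import run_kernel

    n = cell.n_comp
    n_ch = len(cell.channels)
    ch_comp = np.zeros(n_ch, np.int64)
    ch_gmax = np.zeros(n_ch)
    ch_vrev = np.zeros(n_ch)
    ch_power = np.zeros(n_ch, np.int64)
    ch_ca = np.zeros(n_ch, np.int64)
    ch_af = np.zeros(n_ch, np.int64)
    ch_bf = np.zeros(n_ch, np.int64)
    ch_ap = np.zeros((n_ch, 3))
    ch_bp = np.zeros((n_ch, 3))
    ch_dva = np.zeros(n_ch)
    ch_dvb = np.zeros(n_ch)
    ch_sa = np.zeros(n_ch)
    ch_sb = np.zeros(n_ch)
    ch_state = np.zeros(n_ch)
    from .channels import eta_T

    for i, chn in enumerate(cell.channels):
        spec = chn.hh
        ch_comp[i] = chn.comp
        ch_gmax[i] = chn.gmax
        ch_vrev[i] = chn.v_rev * 1e-3
        ch_power[i] = spec.power
        ch_ca[i] = 1 if chn.ca_source else 0
        ch_af[i] = spec.alpha.form
        ch_bf[i] = spec.beta.form
        ch_ap[i] = spec.alpha.params
        ch_bp[i] = spec.beta.params
        ch_dva[i] = spec.dv_alpha
        ch_dvb[i] = spec.dv_beta
        eta = eta_T(spec.q10, cell.t_sim, spec.t_eq)
        ch_sa[i] = eta / spec.tau_alpha
        ch_sb[i] = eta / spec.tau_beta
        ch_state[i] = float(chn.state)

    n_st = len(cell.calcium_stores)
    st_comp = np.zeros(n_st, np.int64)
    st_ca = np.zeros(n_st)
    st_rest = np.zeros(n_st)
    st_pk = np.zeros(n_st)
    st_vp = np.zeros(n_st)
    st_kp = np.zeros(n_st)
    st_il = np.zeros(n_st)
    st_rp = np.zeros(n_st)
    store_of_comp = np.full(n, -1, np.int64)
    for i, st in enumerate(cell.calcium_stores):
        st_comp[i] = st.comp
        st_ca[i] = st.ca
        st_rest[i] = st.ca_rest
        st_pk[i] = st.ca_pk
        st_vp[i] = st.v_pump
        st_kp[i] = st.kappa_in
        st_il[i] = 1.0 / st.tau_leak
        st_rp[i] = st._rest_pump
        store_of_comp[st.comp] = i

    n_sy = len(cell.synapses)
    syn_comp = np.zeros(n_sy, np.int64)
    syn_vmax = np.zeros(n_sy)
    syn_gl = np.zeros(n_sy)
    syn_rmsr = np.zeros(n_sy)
    syn_pool = np.zeros(n_sy)
    for i, syn in enumerate(cell.synapses):
        syn_comp[i] = syn.comp
        syn_vmax[i] = syn.v_rrp_max
        syn_gl[i] = syn.gl
        syn_rmsr[i] = syn.rmsr
        syn_pool[i] = syn.v_rrp

    n_si = len(cell.synaptic_inputs)
    si_comp = np.zeros(n_si, np.int64)
    si_g = np.zeros(n_si)
    si_vrev = np.zeros(n_si)
    si_open = np.zeros((max(n_si, 1), nt))
    for i, s in enumerate(cell.synaptic_inputs):
        si_comp[i] = s.comp
        si_g[i] = s.g_syn
        si_vrev[i] = s.v_rev * 1e-3
        si_open[i] = s.open_fraction
    si_open = si_open[:n_si]

    has_vex = vex_axial is not None
    vex_arr = vex_axial if has_vex else np.zeros((n, 1))
    pool_arr = pool_out if record_pool else np.zeros((n_sy, 1))

    code = run_kernel(u, np.ascontiguousarray(L), np.ascontiguousarray(M0),
                      gm, cm, vr_v, dt, n_settle, nt,
                      np.ascontiguousarray(inj), np.ascontiguousarray(vex_arr),
                      has_vex,
                      ch_comp, ch_gmax, ch_vrev, ch_power, ch_ca,
                      ch_af, ch_ap, ch_bf, ch_bp, ch_dva, ch_dvb,
                      ch_sa, ch_sb, ch_state,
                      st_comp, st_ca, st_rest, st_pk, st_vp, st_kp,
                      st_il, st_rp, store_of_comp,
                      syn_comp, syn_vmax, syn_gl, syn_rmsr, syn_pool,
                      si_comp, si_g, si_vrev, si_open,
                      vm_out, rel_out, ca_out, pool_arr, record_pool)

    for i, chn in enumerate(cell.channels):
        chn.state = float(ch_state[i])
    for i, st in enumerate(cell.calcium_stores):
        st.ca = float(st_ca[i])
    for i, syn in enumerate(cell.synapses):
        syn.v_rrp = float(syn_pool[i])
    return "ok" if code == 0 else "unstable"


def voltage_clamp_screen(cell: CellModel, v_clamp: float = 30.0,
                         t_clamp: float = 0.1, t_recover: float = 0.3,
                         v_ok: float = -30.0, dt: float = 5e-5) -> str:
    """Depolarised-equilibrium screen.

    Clamp the soma to ``v_clamp`` mV for ``t_clamp`` s, release, and check
    whether the somatic membrane potential recovers to ``v_ok`` mV or lower
    within ``t_recover`` s.  Returns ``'ok'``, ``'depolarized_equilibrium'``
    or ``'unstable'``.
    """
    res = simulate(cell, dt=dt, t_total=t_clamp + t_recover,
                   clamp=(cell.soma, v_clamp, 0.0, t_clamp))
    if res.status == "unstable":
        return "unstable"
    v_end = res.vm[cell.soma, -1]
    return "ok" if v_end <= v_ok else "depolarized_equilibrium"
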