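"""Compiled inner loop for active-cell simulations.

The kernel mirrors :func:`cable.simulate`'s Crank-Nicolson / exponential-
Euler stepping exactly for the common case: HH channels whose rate functions
are one of the three closed forms (linoid, exponential, sigmoid), one
optional calcium store per compartment, ribbon synapses and conductance
synaptic inputs, no voltage clamp.  Cells outside this envelope fall back to
the reference numpy path; a test asserts both paths agree.

Rate-form encoding (per gate, alpha and beta independently):
  0: a (V - vh) / expm1(b (V - vh))     params (a, b, vh)
  1: a exp((V - vh)/k)                   params (a, k, vh)
  2: a / (1 + exp((V - vh)/k))           params (a, k, vh)
The stored prefactor scale = eta_T / tau is applied outside the form.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep of the env
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _rate(form, a, b, vh, v):
    x = v - vh
    if form == 0:
        bx = b * x
        if abs(bx) < 1e-9:
            return a / b * (1.0 - bx / 2.0)
        return a * x / math.expm1(bx)
    elif form == 1:
        return a * math.exp(x / b)
    else:
        return a / (1.0 + math.exp(x / b))


@njit(cache=True)
def run_kernel(u, L, M0, gm, cm, vr_v, dt, n_settle, nt,
               inj, vex_axial, has_vex,
               ch_comp, ch_gmax, ch_vrev_v, ch_power, ch_ca_src,
               ch_af, ch_ap, ch_bf, ch_bp, ch_dva, ch_dvb,
               ch_sa, ch_sb, ch_state,
               st_comp, st_ca, st_rest, st_pk, st_vpump, st_kappa,
               st_invleak, st_restpump, store_of_comp,
               syn_comp, syn_vmax, syn_gl, syn_rmsr, syn_pool,
               si_comp, si_g, si_vrev_v, si_open,
               vm_out, rel_out, ca_out, pool_out, record_pool):
    n = u.shape[0]
    n_ch = ch_comp.shape[0]
    n_st = st_comp.shape[0]
    n_sy = syn_comp.shape[0]
    n_si = si_comp.shape[0]
    dt_ms = dt * 1e3
    g_extra = np.zeros(n)
    b_extra = np.zeros(n)
    ca_cur = np.zeros(n)
    status = 0  # 0 ok, 1 unstable

    for step in range(-n_settle, nt):
        k = step
        if k < 0:
            k = 0

        # record (extracellular offset added by the caller)
        if step >= 0:
            for i in range(n):
                vm_out[i, step] = u[i] * 1e3
            for s in range(n_st):
                ca_out[s, step] = st_ca[s]
            for s in range(n_sy):
                c = syn_comp[s]
                so = store_of_comp[c]
                ca = st_ca[so] if so >= 0 else 0.0
                rel_out[s, step] = ca * ca * (syn_pool[s] / syn_vmax[s]) \
                    * syn_gl[s]
                if record_pool:
                    pool_out[s, step] = syn_pool[s]
        if step == nt - 1:
            break

        for i in range(n):
            g_extra[i] = 0.0
            b_extra[i] = inj[i, k]
            ca_cur[i] = 0.0
        for c in range(n_ch):
            i = ch_comp[c]
            st = ch_state[c]
            g = ch_gmax[c]          # g = gmax * state**power
            for _ in range(ch_power[c]):
                g *= st
            g_extra[i] += g
            b_extra[i] += g * ch_vrev_v[c]
            if ch_ca_src[c] == 1:
                ca_cur[i] += g * (u[i] - ch_vrev_v[c])
        for s in range(n_si):
            i = si_comp[s]
            g = si_g[s] * si_open[s, k]
            g_extra[i] += g
            b_extra[i] += g * si_vrev_v[s]
        if has_vex:
            for i in range(n):
                b_extra[i] += vex_axial[i, k]

        # Crank-Nicolson: M = M0 + diag(dt/2 gt/cm);
        # rhs = u + dt/2 (L u - gt u)/cm + dt b
        M = M0.copy()
        rhs = np.empty(n)
        for i in range(n):
            gt = gm[i] + g_extra[i]
            M[i, i] += 0.5 * dt * gt / cm[i]
            lu = 0.0
            for j in range(n):
                lu += L[i, j] * u[j]
            rhs[i] = u[i] + 0.5 * dt * (lu - gt * u[i]) / cm[i] \
                + dt * (gm[i] * vr_v + b_extra[i]) / cm[i]
        u_new = np.linalg.solve(M, rhs)
        bad = False
        for i in range(n):
            if not math.isfinite(u_new[i]) or abs(u_new[i]) > 1.0:
                bad = True
        if bad:
            status = 1
            s0 = step
            if s0 < 0:
                s0 = 0
            for i in range(n):
                for kk in range(s0, nt):
                    vm_out[i, kk] = np.nan
            break
        for i in range(n):
            u[i] = u_new[i]

        # gating states (exact exponential update at frozen V)
        for c in range(n_ch):
            v_mv = u[ch_comp[c]] * 1e3
            a = ch_sa[c] * _rate(ch_af[c], ch_ap[c, 0], ch_ap[c, 1],
                                 ch_ap[c, 2], v_mv - ch_dva[c])
            b = ch_sb[c] * _rate(ch_bf[c], ch_bp[c, 0], ch_bp[c, 1],
                                 ch_bp[c, 2], v_mv - ch_dvb[c])
            tot = a + b
            if tot > 0.0:
                c_inf = a / tot
                cs = c_inf + (ch_state[c] - c_inf) * math.exp(-tot * dt_ms)
                if cs < 0.0:
                    cs = 0.0
                elif cs > 1.0:
                    cs = 1.0
                ch_state[c] = cs

        # calcium stores
        for s in range(n_st):
            i_ca = ca_cur[st_comp[s]]
            if i_ca < 0.0:
                i_ca = -i_ca
            c0 = st_ca[s]
            dcdt = st_kappa[s] * i_ca \
                - st_vpump[s] * c0 / (c0 + st_pk[s]) \
                + st_restpump[s] - (c0 - st_rest[s]) * st_invleak[s]
            c0 = c0 + dt * dcdt
            if c0 < 0.0:
                c0 = 0.0
            st_ca[s] = c0

        # ribbon pools
        for s in range(n_sy):
            c = syn_comp[s]
            so = store_of_comp[c]
            ca = st_ca[so] if so >= 0 else 0.0
            r = ca * ca * (syn_pool[s] / syn_vmax[s]) * syn_gl[s]
            v = syn_pool[s] - r * dt \
                + syn_rmsr[s] * dt * (1.0 - syn_pool[s] / syn_vmax[s])
            if v < 0.0:
                v = 0.0
            elif v > syn_vmax[s]:
                v = syn_vmax[s]
            syn_pool[s] = v

    return status
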