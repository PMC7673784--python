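"""Ion-channel kinetics, calcium handling, ribbon-synapse release and
postsynaptic receptors.

Voltage-gated channels come in two flavours:

* Hodgkin–Huxley (HH) gates: a single activation variable ``c`` with
  voltage-dependent rates alpha/beta, raised to an integer power
  (``g = c**p * gmax``).
* Markov sequential-state channels: a state-occupancy vector advanced by a
  voltage- (and optionally calcium-) dependent generator matrix; the open
  conductance is the summed occupancy of the open states.

All rates carry a Q10 temperature correction
``eta_T = exp(log(Q10) * (Tsim - Teq) / 10)`` and optional inference-time
modifiers: voltage offsets ``dV`` shifting the rate curves and dimensionless
time-constant scalings ``tau`` slowing or speeding the transition.

Transmitter release uses a readily-releasable-pool (RRP) ribbon model: the
instantaneous rate is ``r = ca_uM**2 * (v/vmax) * gl`` vesicles/s, with the
pool replenished at the maximum sustainable release rate ``rmsr``.  Calcium
is tracked in a single sub-membrane shell with a saturable extrusion pump
(half-saturation ``ca_pk``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "eta_T",
    "RateFunction",
    "linoid_rate",
    "exp_rate",
    "sigmoid_rate",
    "HHGateSpec",
    "MarkovChannelSpec",
    "ChannelInstance",
    "cal_rates",
    "channel_conductance",
    "cal_gate_spec",
    "kv_gate_spec",
    "hcn_gate_spec",
    "cat_gate_spec",
    "kir_gate_spec",
    "hh_to_markov",
    "CalciumStore",
    "calcium_update",
    "RibbonSynapse",
    "ribbon_release_rate",
    "rrp_update",
    "PostsynapticReceptor",
    "receptor_drive",
    "PhototransductionSurrogate",
    "photocurrent",
]


def eta_T(q10: float, t_sim: float, t_eq: float) -> float:
    """Temperature correction factor for kinetic rates.

    ``eta_T = exp(log(Q10) * (Tsim - Teq) / 10 K)`` with temperatures in
    degrees Celsius.
    """
    if q10 <= 0:
        raise ValueError("Q10 must be positive")
    return math.exp(math.log(q10) * (t_sim - t_eq) / 10.0)


# ---------------------------------------------------------------------------
# Rate functions
# ---------------------------------------------------------------------------

# Rate functions map membrane voltage (mV) to a rate in 1/ms.  The three
# closed forms below cover every channel shipped with the package; arbitrary
# callables are accepted wherever a RateFunction is expected.
RateFunction = Callable[[np.ndarray], np.ndarray]


def linoid_rate(a: float, b: float, v_half: float) -> RateFunction:
    """Linear-over-exponential rate ``a*(V-vh) / (exp(b*(V-vh)) - 1)``.

    The removable singularity at ``V == v_half`` is replaced by its analytic
    limit ``a/b`` (L'Hopital).
    """

    def rate(v):
        x = np.asarray(v, dtype=float) - v_half
        bx = b * x
        out = np.where(
            np.abs(bx) < 1e-9,
            a / b * (1.0 - bx / 2.0),  # 2nd-order expansion around the pole
            a * x / np.expm1(np.where(np.abs(bx) < 1e-9, 1.0, bx)),
        )
        return out if out.ndim else float(out)

    def scalar(v: float) -> float:
        x = v - v_half
        bx = b * x
        if abs(bx) < 1e-9:
            return a / b * (1.0 - bx / 2.0)
        return a * x / math.expm1(bx)

    rate.scalar = scalar
    rate.form = 0          # linoid; see cable fast path
    rate.params = (a, b, v_half)
    return rate


def exp_rate(a: float, k: float, v_half: float) -> RateFunction:
    """Exponential rate ``a * exp((V - v_half)/k)``."""

    def rate(v):
        x = (np.asarray(v, dtype=float) - v_half) / k
        out = a * np.exp(x)
        return out if out.ndim else float(out)

    rate.scalar = lambda v: a * math.exp((v - v_half) / k)
    rate.form = 1          # exponential
    rate.params = (a, k, v_half)
    return rate


def sigmoid_rate(a: float, k: float, v_half: float) -> RateFunction:
    """Sigmoidal rate ``a / (1 + exp((V - v_half)/k))`` (``k`` < 0 flips the
    direction: the rate then grows with depolarisation)."""

    def rate(v):
        x = (np.asarray(v, dtype=float) - v_half) / k
        out = a / (1.0 + np.exp(x))
        return out if out.ndim else float(out)

    rate.scalar = lambda v: a / (1.0 + math.exp((v - v_half) / k))
    rate.form = 2          # sigmoid
    rate.params = (a, k, v_half)
    return rate


# ---------------------------------------------------------------------------
# HH gates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HHGateSpec:
    """A single HH activation gate with rate modifiers.

    Parameters
    ----------
    alpha, beta:
        Opening/closing rate functions of voltage, units 1/ms at ``Teq``.
    power:
        Integer exponent of the gate in the conductance (3 for CaL, 4 for KV).
    dv_alpha, dv_beta:
        Voltage offsets (mV): rates are evaluated at ``V - dV``.
    tau_alpha, tau_beta:
        Dimensionless time-constant scalings (> 0); rates are divided by them.
    q10, t_eq:
        Temperature sensitivity and the temperature (degC) the rates were
        defined for.
    """

    name: str
    alpha: RateFunction
    beta: RateFunction
    power: int = 1
    dv_alpha: float = 0.0
    dv_beta: float = 0.0
    tau_alpha: float = 1.0
    tau_beta: float = 1.0
    q10: float = 2.0
    t_eq: float = 22.0

    def __post_init__(self):
        if self.tau_alpha <= 0 or self.tau_beta <= 0:
            raise ValueError("tau modifiers must be > 0")

    def with_modifiers(self, dv_alpha=None, dv_beta=None, tau_alpha=None,
                       tau_beta=None) -> "HHGateSpec":
        kw = {}
        if dv_alpha is not None:
            kw["dv_alpha"] = float(dv_alpha)
        if dv_beta is not None:
            kw["dv_beta"] = float(dv_beta)
        if tau_alpha is not None:
            kw["tau_alpha"] = float(tau_alpha)
        if tau_beta is not None:
            kw["tau_beta"] = float(tau_beta)
        return replace(self, **kw)


def cal_rates(v, spec: HHGateSpec, t_sim: float):
    """Evaluate the (modified, temperature-corrected) gate rates at ``v``.

    Returns ``(alpha, beta)`` in 1/ms:
    ``alpha = eta_T/tau_a * alpha0(V - dVa)`` and analogously for beta.
    """
    eta = eta_T(spec.q10, t_sim, spec.t_eq)
    a = eta / spec.tau_alpha * np.asarray(spec.alpha(np.asarray(v) - spec.dv_alpha))
    b = eta / spec.tau_beta * np.asarray(spec.beta(np.asarray(v) - spec.dv_beta))
    return a, b


def channel_conductance(state, gmax: float, power: int = 1,
                        open_states: Sequence[int] | None = None) -> float:
    """Conductance from a gating state.

    HH: ``g = c**power * gmax`` (``state`` scalar in [0, 1]).
    Markov: ``g = sum(occupancy[open_states]) * gmax`` (``state`` a vector).
    """
    state = np.asarray(state, dtype=float)
    if state.ndim == 0:
        c = float(state)
        if not 0.0 <= c <= 1.0 + 1e-12:
            raise ValueError("HH gate state outside [0, 1]")
        return c ** power * gmax
    if open_states is None:
        raise ValueError("Markov state requires open_states")
    return float(state[list(open_states)].sum()) * gmax


# ---------------------------------------------------------------------------
# Markov channels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkovChannelSpec:
    """Generic Markov sequential-state channel.

    ``generator(V, ca_uM)`` must return a (k, k) rate matrix Q in 1/ms with
    ``Q[i, j]`` the i->j transition rate for ``i != j`` and rows summing to
    zero (probability conservation).  ``surrogate=True`` marks bundled
    approximations whose state tables are not literature transcriptions.
    """

    name: str
    n_states: int
    open_states: tuple
    generator: Callable[[float, float], np.ndarray]
    q10: float = 2.0
    t_eq: float = 22.0
    surrogate: bool = False

    def rate_matrix(self, v: float, ca_uM: float, t_sim: float) -> np.ndarray:
        q = np.asarray(self.generator(v, ca_uM), dtype=float)
        if q.shape != (self.n_states, self.n_states):
            raise ValueError("generator returned wrong shape")
        # enforce row consistency: diagonal balances off-diagonal outflow
        q = q.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return eta_T(self.q10, t_sim, self.t_eq) * q


@dataclass
class ChannelInstance:
    """A channel population in one compartment.

    ``gmax`` is the total maximum conductance in siemens (density already
    multiplied by the compartment surface area), ``v_rev`` the reversal
    potential in mV.  Exactly one of ``hh``/``markov`` is set.
    """

    comp: int
    gmax: float
    v_rev: float
    hh: HHGateSpec | None = None
    markov: MarkovChannelSpec | None = None
    ca_source: bool = False  # current feeds a CalciumStore
    state: np.ndarray | float | None = field(default=None)

    def __post_init__(self):
        if (self.hh is None) == (self.markov is None):
            raise ValueError("exactly one of hh/markov must be given")

    def init_state(self, v: float, t_sim: float) -> None:
        if self.hh is not None:
            a, b = cal_rates(v, self.hh, t_sim)
            tot = float(a) + float(b)
            self.state = float(a) / tot if tot > 0 else 0.0
        else:
            # stationary distribution of the generator at v
            q = self.markov.rate_matrix(v, 0.05, t_sim)
            k = q.shape[0]
            m = np.vstack([q.T, np.ones(k)])
            rhs = np.zeros(k + 1)
            rhs[-1] = 1.0
            occ, *_ = np.linalg.lstsq(m, rhs, rcond=None)
            occ = np.clip(occ, 0.0, None)
            self.state = occ / occ.sum()

    def conductance(self) -> float:
        if self.hh is not None:
            return float(self.state) ** self.hh.power * self.gmax
        return channel_conductance(self.state, self.gmax,
                                   open_states=self.markov.open_states)

    def advance(self, v: float, ca_uM: float, dt_ms: float, t_sim: float) -> None:
        """Advance the gating state by ``dt_ms`` with rates frozen at ``v``.

        HH gates use the exact single-step solution (exponential Euler);
        Markov occupancies use the matrix exponential of the frozen
        generator, which conserves total probability to round-off.
        """
        if self.hh is not None:
            spec = self.hh
            fa = getattr(spec.alpha, "scalar", None)
            fb = getattr(spec.beta, "scalar", None)
            cache = self.__dict__.get("_eta_cache")
            if cache is not None and cache[0] == t_sim:
                eta = cache[1]
            else:
                eta = eta_T(spec.q10, t_sim, spec.t_eq)
                self.__dict__["_eta_cache"] = (t_sim, eta)
            if fa is not None and fb is not None:
                a = eta / spec.tau_alpha * fa(v - spec.dv_alpha)
                b = eta / spec.tau_beta * fb(v - spec.dv_beta)
            else:
                a, b = cal_rates(v, spec, t_sim)
                a = float(a)
                b = float(b)
            tot = a + b
            if tot <= 0:
                return
            c_inf = a / tot
            c = c_inf + (float(self.state) - c_inf) * math.exp(-tot * dt_ms)
            # rate functions are expected to be non-negative on the admissible
            # range; clamp to guard user-supplied kinetics
            self.state = min(max(c, 0.0), 1.0)
        else:
            from scipy.linalg import expm

            q = self.markov.rate_matrix(v, ca_uM, t_sim)
            self.state = np.asarray(self.state) @ expm(q * dt_ms)


# ---------------------------------------------------------------------------
# Shipped channel specs
# ---------------------------------------------------------------------------


def cal_gate_spec(q10: float = 2.0, t_eq: float = 22.0, **mods) -> HHGateSpec:
    """L-type calcium channel activation gate (power 3).

    alpha(V) = -0.04 (V+15) / (exp(-0.04 (V+15)) - 1)  [1/ms]
    beta(V)  = 5 exp(-(V+38)/18)                        [1/ms]
    """
    return HHGateSpec(
        name="CaL",
        alpha=linoid_rate(a=-0.04, b=-0.04, v_half=-15.0),
        beta=exp_rate(a=5.0, k=-18.0, v_half=-38.0),
        power=3,
        q10=q10,
        t_eq=t_eq,
    ).with_modifiers(**mods)


def kv_gate_spec(q10: float = 2.0, t_eq: float = 6.3, **mods) -> HHGateSpec:
    """Delayed-rectifier potassium gate (power 4), classic squid kinetics.

    alpha(V) = 0.01 (V+55) / (1 - exp(-(V+55)/10)); beta = 0.125 exp(-(V+65)/80).
    (``1 - exp(bx) = -expm1(bx)``, hence the negated prefactor.)
    """
    return HHGateSpec(
        name="KV",
        alpha=linoid_rate(a=-0.01, b=-0.1, v_half=-55.0),
        beta=exp_rate(a=0.125, k=-80.0, v_half=-65.0),
        power=4,
        q10=q10,
        t_eq=t_eq,
    ).with_modifiers(**mods)


def hcn_gate_spec(v_half: float = -85.0, slope: float = 8.0,
                  tau_ms: float = 80.0, q10: float = 2.0,
                  t_eq: float = 35.0) -> HHGateSpec:
    """Hyperpolarisation-activated (HCN-like) gate, power 1.

    HH-style surrogate for the 10-state Markov HCN channel: sigmoidal
    activation opening below ``v_half`` with a voltage-independent time
    constant ``tau_ms``.
    """
    a0 = 1.0 / tau_ms
    return HHGateSpec(name="HCN",
                      alpha=sigmoid_rate(a0, slope, v_half),
                      beta=sigmoid_rate(a0, -slope, v_half),
                      power=1, q10=q10, t_eq=t_eq)


def cat_gate_spec(v_half: float = -50.0, slope: float = 6.0,
                  tau_ms: float = 10.0, q10: float = 2.0,
                  t_eq: float = 35.0, **mods) -> HHGateSpec:
    """Low-threshold transient (CaT-like) activation gate, power 2.

    HH-style surrogate for the 12-state Markov CaT channel: activates at
    substantially more hyperpolarised potentials than CaL.  Inactivation is
    omitted; the low threshold is what matters for transient sensitivity.
    """
    a0 = 1.0 / tau_ms
    return HHGateSpec(name="CaT",
                      alpha=sigmoid_rate(a0, -slope, v_half),
                      beta=sigmoid_rate(a0, slope, v_half),
                      power=2, q10=q10, t_eq=t_eq).with_modifiers(**mods)


def kir_gate_spec(v_half: float = -70.0, slope: float = 10.0,
                  tau_ms: float = 5.0, q10: float = 2.0,
                  t_eq: float = 35.0) -> HHGateSpec:
    """Inward-rectifier potassium gate (power 1), HH-style surrogate for the
    3-state Markov Kir channel: conductance increases with hyperpolarisation."""
    a0 = 1.0 / tau_ms
    return HHGateSpec(name="Kir",
                      alpha=sigmoid_rate(a0, slope, v_half),
                      beta=sigmoid_rate(a0, -slope, v_half),
                      power=1, q10=q10, t_eq=t_eq)


def hh_to_markov(spec: HHGateSpec) -> MarkovChannelSpec:
    """Mechanical expansion of an HH gate of power p into its (p+1)-state
    Markov chain.

    States 0..p hold 0..p open subunits; forward rate from state i is
    ``(p - i) * alpha`` and backward ``i * beta``.  The single open state is
    state p, so the open occupancy equals ``c**p`` whenever the occupancy is
    binomial — which the chain preserves exactly.
    """
    p = spec.power

    def generator(v, ca_uM):
        # rates without eta_T: the Markov wrapper applies its own Q10 factor,
        # configured identically below.
        a = float(np.asarray(spec.alpha(v - spec.dv_alpha))) / spec.tau_alpha
        b = float(np.asarray(spec.beta(v - spec.dv_beta))) / spec.tau_beta
        q = np.zeros((p + 1, p + 1))
        for i in range(p):
            q[i, i + 1] = (p - i) * a
            q[i + 1, i] = (i + 1) * b
        return q

    return MarkovChannelSpec(
        name=spec.name + "_MS",
        n_states=p + 1,
        open_states=(p,),
        generator=generator,
        q10=spec.q10,
        t_eq=spec.t_eq,
        surrogate=True,
    )


# ---------------------------------------------------------------------------
# Calcium store
# ---------------------------------------------------------------------------


@dataclass
class CalciumStore:
    """Single-shell sub-membrane calcium concentration [Ca]0 (uM).

    d[Ca]0/dt = kappa_in*|i_ca| - v_pump*[Ca]0/([Ca]0 + ca_pk)
                - ([Ca]0 - ca_rest)/tau_leak + pump_rest_balance

    ``kappa_in`` converts calcium current (A) to uM/s; ``ca_pk`` is the pump
    half-saturation, ``v_pump`` the maximal extrusion rate (uM/s).  The
    constant ``pump_rest_balance`` offsets the pump at rest so that
    ``i_ca = 0, [Ca]0 = ca_rest`` is an exact equilibrium.
    """

    comp: int = 0
    ca: float = 0.05
    ca_rest: float = 0.05
    ca_pk: float = 0.5
    v_pump: float = 50.0
    kappa_in: float = 5.0e12
    tau_leak: float = 0.5

    def __post_init__(self):
        if self.ca < 0:
            raise ValueError("[Ca]0 must be >= 0")
        self._rest_pump = self.v_pump * self.ca_rest / (self.ca_rest + self.ca_pk)

    def pump_rate(self, ca: float | None = None) -> float:
        ca = self.ca if ca is None else ca
        return self.v_pump * ca / (ca + self.ca_pk)


def calcium_update(store: CalciumStore, i_ca: float, dt: float) -> CalciumStore:
    """Advance the calcium store by ``dt`` seconds given a calcium current
    ``i_ca`` (A, magnitude used).  Returns the store (updated in place)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c = store.ca
    dcdt = (
        store.kappa_in * abs(i_ca)
        - store.pump_rate(c)
        + store._rest_pump
        - (c - store.ca_rest) / store.tau_leak
    )
    store.ca = max(0.0, c + dt * dcdt)
    return store


# ---------------------------------------------------------------------------
# Ribbon synapse
# ---------------------------------------------------------------------------


@dataclass
class RibbonSynapse:
    """Ribbon synapse with a readily releasable pool.

    ``v_rrp_max``: pool capacity (vesicles); ``gl``: linear release gain;
    ``rmsr``: replenishment / maximum sustainable release rate (ves/s).
    """

    comp: int = 0
    v_rrp_max: float = 12.0
    gl: float = 1.0
    rmsr: float = 8.0
    v_rrp: float | None = None

    def __post_init__(self):
        if self.v_rrp is None:
            self.v_rrp = self.v_rrp_max
        if not 0.0 <= self.v_rrp <= self.v_rrp_max:
            raise ValueError("v_rrp outside [0, v_rrp_max]")


def ribbon_release_rate(ca_uM: float, syn: RibbonSynapse) -> float:
    """Instantaneous release rate ``r = ca_uM**2 * (vRRP/vRRPmax) * gl`` in
    vesicles/s (calcium in uM)."""
    if ca_uM < 0:
        raise ValueError("calcium must be >= 0")
    return (ca_uM ** 2) * (syn.v_rrp / syn.v_rrp_max) * syn.gl


def rrp_update(syn: RibbonSynapse, r: float, dt: float) -> RibbonSynapse:
    """Pool update ``v <- v - r*dt + rmsr*dt*(1 - v/vmax)``, clipped to
    ``[0, vmax]``.  Returns the synapse (updated in place)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v = syn.v_rrp
    v = v - r * dt + syn.rmsr * dt * (1.0 - v / syn.v_rrp_max)
    syn.v_rrp = min(max(v, 0.0), syn.v_rrp_max)
    return syn


# ---------------------------------------------------------------------------
# Postsynaptic receptors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PostsynapticReceptor:
    """Cone->BC receptor.

    ``kind='kainate'`` is sign-preserving (OFF pathway): transmitter opens the
    channel with first-order kinetics of time constant ``tau_gamma`` (ms).
    ``kind='mglur6'`` is sign-inverting (ON pathway): the open fraction
    decreases with transmitter via a saturating map, low-pass filtered with
    ``tau_gamma``.  ``stc`` scales the transmitter concentration seen by the
    receptor; ``g_contact`` is the conductance per synaptic contact (S).
    """

    kind: str = "kainate"
    stc: float = 1.0
    tau_gamma: float = 20.0
    g_contact: float = 0.25e-9
    half_glu: float = 20.0  # release rate (ves/s) at half activation

    def __post_init__(self):
        if self.kind not in ("kainate", "mglur6"):
            raise ValueError("kind must be 'kainate' or 'mglur6'")


def receptor_drive(glu: np.ndarray, rec: PostsynapticReceptor,
                   dt: float) -> np.ndarray:
    """Open-fraction trace from a presynaptic release-rate trace (ves/s).

    The transmitter signal is ``stc * glu``; the steady-state open fraction is
    ``T/(T + half)`` for kainate and ``half/(T + half)`` for mGluR6, relaxed
    towards with time constant ``tau_gamma`` (exact per-step exponential).
    """
    glu = np.asarray(glu, dtype=float)
    if np.any(glu < 0):
        raise ValueError("release rates must be >= 0")
    t = rec.stc * glu
    if rec.kind == "kainate":
        target = t / (t + rec.half_glu)
    else:
        target = rec.half_glu / (t + rec.half_glu)
    out = np.empty_like(target)
    out[0] = target[0]
    decay = math.exp(-dt * 1e3 / rec.tau_gamma)
    o = out[0]
    for i in range(1, len(target)):
        o = target[i] + (o - target[i]) * decay
        out[i] = o
    return out


# ---------------------------------------------------------------------------
# Phototransduction surrogate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhototransductionSurrogate:
    """Low-pass cascade with divisive adaptation mapping photon absorption
    rate (P*/s per cone) to a hyperpolarising inner-segment current (A).

    Steady state: ``I = -gain * y/(1 + w*y_slow)`` with ``y`` the fast-filtered
    photon rate and ``y_slow`` a slower adaptation signal; steady current is
    monotone (more photons, more hyperpolarising) and saturating.
    """

    gain: float = 4.0e-16       # A per (P*/s) before adaptation
    tau_fast: float = 25.0      # ms
    tau_slow: float = 250.0     # ms
    w_adapt: float = 3.0e-5     # 1/(P*/s)
    i_dark: float = 0.0         # constant dark current offset (A)

    def steady_current(self, rate: float) -> float:
        return -self.gain * rate / (1.0 + self.w_adapt * rate) + self.i_dark


def photocurrent(photon_rate: np.ndarray, spec: PhototransductionSurrogate,
                 dt: float) -> np.ndarray:
    """Hyperpolarising current trace (A) from a photon-rate trace (P*/s).

    Two cascaded first-order stages (fast drive, slow adaptation) with exact
    per-step exponential updates; initial state is the steady state at the
    first sample.
    """
    p = np.asarray(photon_rate, dtype=float)
    if np.any(p < 0):
        raise ValueError("photon rates must be >= 0")
    df = math.exp(-dt * 1e3 / spec.tau_fast)
    ds = math.exp(-dt * 1e3 / spec.tau_slow)
    y = p[0]
    ys = p[0]
    out = np.empty_like(p)
    for i in range(len(p)):
        if i > 0:
            y = p[i] + (y - p[i]) * df
            ys = p[i] + (ys - p[i]) * ds
        out[i] = -spec.gain * y / (1.0 + spec.w_adapt * ys) + spec.i_dark
    return out
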