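"""Ready-made cell models.

Builders assemble :class:`cable.CellModel` instances from the morphology and
channel primitives:

* a four-compartment cone with L-type calcium channels, a calcium store and
  a ribbon synapse at the terminal, KV and HCN at the inner segment, driven
  by the phototransduction surrogate;
* a reduced bipolar-cell ("BC toy") with dendrite, soma, axon and terminal
  compartments, used for parameter-recovery experiments;
* a pair of single-terminal toys differing only in their terminal calcium
  channel (low-threshold transient CaT vs high-threshold sustained CaL),
  used to exercise selective electrical stimulation.

Default parameter values are package calibrations chosen so that resting
release rates and light/stimulus-evoked excursions fall inside the
plausibility bands used by the discrepancy penalties.
"""

from __future__ import annotations

import math

import numpy as np

from . import channels as ch
from .cable import CellModel, SynapticInput, simulate
from .morphology import Compartment, MembraneSpec, compartmentalize, \
    cone_morphology

__all__ = [
    "make_passive_cell",
    "make_cable_cell",
    "make_cone_cell",
    "make_bc_toy_cell",
    "BC_TOY_BOUNDS",
    "BC_TOY_TRUTH",
    "make_selectivity_toys",
    "CONE_RMSR",
    "BC_RMSR",
]

CONE_RMSR = 100.0  # vesicles/s
BC_RMSR = 8.0      # vesicles/s


def make_passive_cell(n: int = 1, Rm: float = 1.3e4, Cm: float = 1.18,
                      Ri: float = 132.0, vr: float = -60.0,
                      area_um2: float = 1000.0,
                      length_um: float = 10.0) -> CellModel:
    """A chain of ``n`` identical passive cylinder compartments."""
    comps = []
    for i in range(n):
        neigh = tuple(j for j in (i - 1, i + 1) if 0 <= j < n)
        comps.append(Compartment(i, neigh, "cylinder", length_um, area_um2,
                                 np.array([0.0, 0.0, i * length_um]), "S"))
    comps = compartmentalize(comps, MembraneSpec(Rm, Cm, Ri, vr))
    return CellModel(compartments=comps, vr=vr)


def make_cable_cell(comps, vr: float = -60.0, t_sim: float = 37.0,
                    **kwargs) -> CellModel:
    return CellModel(compartments=comps, vr=vr, t_sim=t_sim, **kwargs)


# ---------------------------------------------------------------------------
# Cone
# ---------------------------------------------------------------------------


def make_cone_cell(Rm: float = 2.0e4, Cm: float = 1.18, vr: float = -27.0,
                   g_cal: float = 2.0e-9, g_kv: float = 0.5e-9,
                   g_hcn: float = 0.15e-9,
                   gl: float = 250.0, v_rrp_max: float = 25.0,
                   ca_pk: float = 0.8, kappa_in: float = 6.0e15,
                   t_sim: float = 37.0) -> CellModel:
    """The four-compartment cone (OS, IS/S, A, AT).

    Phototransduction current enters the inner segment (compartment 1);
    calcium enters the terminal through CaL and drives the ribbon with
    replenishment rate 100 ves/s.  Conductances are totals in siemens.
    """
    comps = compartmentalize(cone_morphology(), MembraneSpec(Rm, Cm, 132.0, vr))
    cal = ch.ChannelInstance(comp=3, gmax=g_cal, v_rev=40.0,
                             hh=ch.cal_gate_spec(t_eq=t_sim), ca_source=True)
    kv = ch.ChannelInstance(comp=1, gmax=g_kv, v_rev=-80.0,
                            hh=ch.kv_gate_spec(t_eq=t_sim))
    hcn = ch.ChannelInstance(comp=1, gmax=g_hcn, v_rev=-30.0,
                             hh=ch.hcn_gate_spec(v_half=-65.0, t_eq=t_sim))
    store = ch.CalciumStore(comp=3, ca_pk=ca_pk, kappa_in=kappa_in,
                            v_pump=80.0)
    ribbon = ch.RibbonSynapse(comp=3, v_rrp_max=v_rrp_max, gl=gl,
                              rmsr=CONE_RMSR)
    cell = CellModel(compartments=comps, vr=vr, t_sim=t_sim,
                     channels=[cal, kv, hcn], synapses=[ribbon],
                     calcium_stores=[store], soma=1,
                     light_collecting_area_um2=0.2)
    return cell


def cone_light_response(cell: CellModel, photon_rate: np.ndarray, dt: float,
                        settle: float = 2.0,
                        photo: ch.PhototransductionSurrogate | None = None):
    """Simulate the cone under a photon-rate trace (P*/s/cone).

    The phototransduction surrogate converts the photon rate to an inner-
    segment current; the cell is settled for ``settle`` seconds under the
    first sample before recording starts.
    """
    if photo is None:
        photo = ch.PhototransductionSurrogate()
    i_photo = ch.photocurrent(photon_rate, photo, dt)
    inj = np.zeros((cell.n_comp, len(i_photo)))
    inj[1] = i_photo
    return simulate(cell, dt=dt, t_total=(len(i_photo) - 1) * dt,
                    i_inj=inj, settle=settle)


# ---------------------------------------------------------------------------
# Reduced bipolar cell
# ---------------------------------------------------------------------------


def _bc_toy_compartments(Rm: float, Cm: float, vr: float):
    geo = [
        # (shape, length um, area um2, center, region)
        ("cylinder", 10.0, math.pi * 1.5 * 10.0, (0, 0, 18), "PD"),
        ("sphere", 8.0, math.pi * 8.0 ** 2, (0, 0, 10), "S"),
        ("cylinder", 20.0, math.pi * 1.2 * 20.0, (0, 0, -4), "DA"),
        ("sphere", 3.0, math.pi * 3.0 ** 2, (0, 0, -16), "AT"),
    ]
    comps = []
    for i, (shape, lc, area, center, region) in enumerate(geo):
        neigh = tuple(j for j in (i - 1, i + 1) if 0 <= j < len(geo))
        comps.append(Compartment(i, neigh, shape, lc, area,
                                 np.array(center, float), region))
    return compartmentalize(comps, MembraneSpec(Rm, Cm, 132.0, vr))


# Free-parameter box for the four-parameter recovery experiment (totals in
# siemens for conductances) and the generating ground truth.
BC_TOY_BOUNDS = {
    "g_cal": (0.2e-9, 3.0e-9),
    "g_kv": (0.0, 2.0e-9),
    "gl": (10.0, 150.0),
    "v_rrp_max": (4.0, 16.0),
}
BC_TOY_TRUTH = {"g_cal": 1.2e-9, "g_kv": 0.6e-9, "gl": 60.0,
                "v_rrp_max": 9.0}


def make_bc_toy_cell(g_cal: float = 1.2e-9, g_kv: float = 0.6e-9,
                     gl: float = 60.0, v_rrp_max: float = 9.0,
                     Rm: float = 1.3e4, Cm: float = 1.18, vr: float = -60.0,
                     g_syn: float = 0.3e-9, receptor: str = "kainate",
                     t_sim: float = 37.0) -> CellModel:
    """Four-compartment OFF-style bipolar cell toy.

    CaL (calcium source) at the terminal drives the ribbon (rmsr = 8 ves/s);
    KV sits on the axon.  Cone input arrives through a kainate (sign-
    preserving) or mGluR6 (sign-inverting) receptor conductance on the
    dendrite; attach the open-fraction trace via ``bc_light_response``.
    """
    comps = _bc_toy_compartments(Rm, Cm, vr)
    chans = [
        ch.ChannelInstance(comp=3, gmax=g_cal, v_rev=40.0,
                           hh=ch.cal_gate_spec(t_eq=t_sim), ca_source=True),
    ]
    if g_kv > 0:
        chans.append(ch.ChannelInstance(comp=2, gmax=g_kv, v_rev=-80.0,
                                        hh=ch.kv_gate_spec(t_eq=t_sim)))
    store = ch.CalciumStore(comp=3, ca_pk=0.5, kappa_in=1.5e15, v_pump=200.0,
                            tau_leak=0.1)
    ribbon = ch.RibbonSynapse(comp=3, v_rrp_max=v_rrp_max, gl=gl,
                              rmsr=BC_RMSR)
    cell = CellModel(compartments=comps, vr=vr, t_sim=t_sim, channels=chans,
                     synapses=[ribbon], calcium_stores=[store], soma=1,
                     metadata={"g_syn": g_syn, "receptor": receptor})
    return cell


def bc_light_response(cell: CellModel, open_fraction: np.ndarray, dt: float,
                      settle: float = 1.0, v_rev_syn: float = 0.0):
    """Simulate the BC toy under a synaptic open-fraction trace in [0, 1]."""
    g_syn = cell.metadata.get("g_syn", 0.3e-9)
    cell.synaptic_inputs = [SynapticInput(comp=0, g_syn=g_syn,
                                          v_rev=v_rev_syn,
                                          open_fraction=np.asarray(open_fraction,
                                                                   float))]
    return simulate(cell, dt=dt, t_total=(len(open_fraction) - 1) * dt,
                    settle=settle)


# ---------------------------------------------------------------------------
# Selectivity toys
# ---------------------------------------------------------------------------


def make_selectivity_toys(t_sim: float = 33.5):
    """(transient_cell, sustained_cell) for stimulus-selectivity searches.

    Both are two-compartment cells (soma + terminal) with identical passive
    properties and ribbons; they differ only in the terminal calcium channel:
    the transient cell carries a fast low-threshold (CaT-like) gate, the
    sustained cell a slow higher-threshold (CaL-like) gate that only opens
    for prolonged depolarisation.  Cone input is absent (photoreceptor-
    degenerated setting); stimulation must act through the extracellular
    field.
    """

    def build(kind: str) -> CellModel:
        geo = [
            ("sphere", 8.0, math.pi * 8.0 ** 2, (0, 0, 30.0), "S"),
            ("sphere", 3.0, math.pi * 3.0 ** 2, (0, 0, 12.0), "AT"),
        ]
        comps = []
        for i, (shape, lc, area, center, region) in enumerate(geo):
            neigh = tuple(j for j in (i - 1, i + 1) if 0 <= j < len(geo))
            comps.append(Compartment(i, neigh, shape, lc, area,
                                     np.array(center, float), region))
        comps = compartmentalize(comps, MembraneSpec(1.3e4, 1.18, 132.0, -55.0))
        if kind == "transient":
            gate = ch.cat_gate_spec(v_half=-40.0, slope=4.0, tau_ms=3.0,
                                    t_eq=t_sim)
            gmax = 1.2e-9
        else:
            gate = ch.cat_gate_spec(v_half=-30.0, slope=5.0, tau_ms=40.0,
                                    t_eq=t_sim)
            gmax = 1.5e-9
        ca_chan = ch.ChannelInstance(comp=1, gmax=gmax, v_rev=40.0, hh=gate,
                                     ca_source=True)
        store = ch.CalciumStore(comp=1, ca_pk=0.5, kappa_in=1.5e15,
                                v_pump=200.0, tau_leak=0.1)
        ribbon = ch.RibbonSynapse(comp=1, v_rrp_max=9.0, gl=55.0, rmsr=BC_RMSR)
        return CellModel(compartments=comps, vr=-55.0, t_sim=t_sim,
                         channels=[ca_chan], synapses=[ribbon],
                         calcium_stores=[store], soma=0,
                         metadata={"kind": kind})

    return build("transient"), build("sustained")


def compartment_centers_um(cell: CellModel) -> np.ndarray:
    return np.stack([c.center for c in cell.compartments])
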