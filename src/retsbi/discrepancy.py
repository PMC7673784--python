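"""Measurement forward model and the seven-component discrepancy.

The fluorescence proxy for a glutamate-release trace is the causal
convolution with an exponential indicator kernel, ``kappa(t) = exp(-t/60 ms)``
(unnormalised; the affine fit below absorbs scale).  The trace discrepancy is
the variance-normalised squared residual after the best affine map of the
simulation onto the target with a non-negative slope:

    d_iGluSnFR = min_{a, b>=0} ||target - (a + b sim)||^2 / ||target - mean||^2

Scalar quantities (resting rates and voltages, response ranges, extrema) are
penalised with a smooth bounded function that is zero inside a free interval
[tl, tu] and saturates at -1 / +1 outside, parameterised by outer bounds
pl / pu where the penalty reaches -(1 - e^-2) / +(1 - e^-2).

The total discrepancy is the L1 norm of the signed component vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "IGLUSNFR_TAU_S",
    "PenaltyBounds",
    "DiscrepancyVector",
    "iglusnfr_from_release",
    "delta_iglusnfr",
    "bounded_penalty",
    "response_deltas",
    "discrepancy_vector",
    "peak_time_differences",
    "CONE_BOUNDS",
    "OFF_BC_BOUNDS",
    "ON_BC_BOUNDS",
    "penalty_bounds_for",
]

IGLUSNFR_TAU_S = 0.060
COMPONENT_NAMES = ("iGluSnFR", "RateRest", "VRest", "RateDelta", "VDelta",
                   "VMin", "VMax")


@dataclass(frozen=True)
class PenaltyBounds:
    """Outer/inner penalty bounds ``pl <= tl <= tu <= pu`` (infinities allowed;
    an infinite t-bound disables the corresponding branch)."""

    pl: float
    tl: float
    tu: float
    pu: float

    def __post_init__(self):
        if not (self.pl <= self.tl <= self.tu <= self.pu):
            raise ValueError("bounds must satisfy pl <= tl <= tu <= pu")


# Published penalty tables.  Release-rate bounds in vesicles/s, voltages in
# mV.  Where the printed table and the accompanying text disagree on the
# OFF/ON ordering, the text values are used (OFF resting-rate tu = 4 ves/s,
# ON tu = 3 ves/s; voltage-range tu = 25 mV OFF, 15 mV ON); the cone VMin
# row is read as pl = -75, tl = -60.
INF = math.inf
CONE_BOUNDS = {
    "RateRest": PenaltyBounds(0.0, 50.0, 80.0, 100.0),
    "VRest": PenaltyBounds(-80.0, -55.0, -40.0, -20.0),
    "RateDelta": PenaltyBounds(0.0, 50.0, 65.0, 100.0),
    "VDelta": PenaltyBounds(0.0, 5.0, 10.0, 20.0),
    "VMin": PenaltyBounds(-75.0, -60.0, INF, INF),
    "VMax": PenaltyBounds(-INF, -INF, -35.0, -20.0),
}
OFF_BC_BOUNDS = {
    "RateRest": PenaltyBounds(0.0, 0.0, 4.0, 7.0),
    "VRest": PenaltyBounds(-80.0, -65.0, -45.0, -30.0),
    "RateDelta": PenaltyBounds(0.0, 5.0, INF, INF),
    "VDelta": PenaltyBounds(0.0, 5.0, 25.0, 40.0),
    "VMin": PenaltyBounds(-100.0, -80.0, INF, INF),
    "VMax": PenaltyBounds(-INF, -INF, -10.0, 0.0),
}
ON_BC_BOUNDS = {
    "RateRest": PenaltyBounds(0.0, 0.0, 3.0, 7.0),
    "VRest": PenaltyBounds(-80.0, -65.0, -45.0, -30.0),
    "RateDelta": PenaltyBounds(0.0, 5.0, INF, INF),
    "VDelta": PenaltyBounds(0.0, 5.0, 15.0, 40.0),
    "VMin": PenaltyBounds(-100.0, -80.0, INF, INF),
    "VMax": PenaltyBounds(-INF, -INF, -10.0, 0.0),
}


def penalty_bounds_for(cell_class: str) -> dict:
    """Bound table for ``'cone'``, ``'off_bc'`` or ``'on_bc'``."""
    try:
        return {"cone": CONE_BOUNDS, "off_bc": OFF_BC_BOUNDS,
                "on_bc": ON_BC_BOUNDS}[cell_class]
    except KeyError:
        raise ValueError(f"unknown cell class {cell_class!r}") from None


@dataclass(frozen=True)
class DiscrepancyVector:
    """The seven named components.  ``iGluSnFR >= 0``; the six bounded
    penalties are signed with magnitude <= 1; ``total`` is the L1 norm."""

    iGluSnFR: float
    RateRest: float
    VRest: float
    RateDelta: float
    VDelta: float
    VMin: float
    VMax: float

    @property
    def total(self) -> float:
        return float(sum(abs(v) for v in self.as_array()))

    def as_array(self) -> np.ndarray:
        return np.array([self.iGluSnFR, self.RateRest, self.VRest,
                         self.RateDelta, self.VDelta, self.VMin, self.VMax])


def iglusnfr_from_release(release: np.ndarray, dt: float,
                          tau: float = IGLUSNFR_TAU_S,
                          truncate: float = 5.0) -> np.ndarray:
    """Causal convolution of a release-rate trace with the exponential
    indicator kernel ``exp(-t/tau)`` sampled on the grid, truncated at
    ``truncate`` time constants.  Output has the input's length."""
    r = np.asarray(release, dtype=float)
    nk = int(round(truncate * tau / dt)) + 1
    kernel = np.exp(-np.arange(nk) * dt / tau)
    return np.convolve(r, kernel)[: len(r)]


def delta_iglusnfr(target: np.ndarray, sim: np.ndarray) -> float:
    """Affine-invariant normalised distance (Eq. above), in [0, 1] whenever
    the non-negativity constraint on the slope binds at the worst case."""
    t = np.asarray(target, dtype=float)
    s = np.asarray(sim, dtype=float)
    if t.shape != s.shape:
        raise ValueError("traces must have equal length")
    t_var = float(np.sum((t - t.mean()) ** 2))
    if t_var == 0:
        raise ValueError("target trace is constant (zero variance)")
    s_var = float(np.sum((s - s.mean()) ** 2))
    if s_var == 0:
        b = 0.0
    else:
        b = float(np.sum((t - t.mean()) * (s - s.mean()))) / s_var
        b = max(b, 0.0)
    a = t.mean() - b * s.mean()
    return float(np.sum((t - (a + b * s)) ** 2)) / t_var


def bounded_penalty(y: float, b: PenaltyBounds) -> float:
    """Signed penalty in [-1, 1]: zero on [tl, tu], saturating smoothly
    outside; equals -(1 - e^-2) at pl and +(1 - e^-2) at pu."""
    if math.isfinite(b.tl) and y < b.tl:
        width = b.tl - b.pl
        if width == 0:
            return -1.0
        return -1.0 + math.exp(-2.0 * (y - b.tl) ** 2 / width ** 2)
    if math.isfinite(b.tu) and y > b.tu:
        width = b.pu - b.tu
        if width == 0:
            return 1.0
        return 1.0 - math.exp(-2.0 * (y - b.tu) ** 2 / width ** 2)
    return 0.0


def response_deltas(release: np.ndarray, v_soma: np.ndarray,
                    r_rest: float, v_rest: float) -> tuple[float, float]:
    """Largest absolute excursions from rest after stimulus onset:
    ``(max|r - r0|, max|v - v0|)``."""
    r = np.asarray(release, dtype=float)
    v = np.asarray(v_soma, dtype=float)
    return (float(np.max(np.abs(r - r_rest))),
            float(np.max(np.abs(v - v_rest))))


def discrepancy_vector(target: np.ndarray, sim_fluor: np.ndarray,
                       release: np.ndarray, v_soma: np.ndarray,
                       r_rest: float, v_rest: float,
                       bounds: dict) -> DiscrepancyVector:
    """Assemble all seven components.

    ``release`` is the release-rate trace used for the scalar penalties (for
    bipolar cells: the mean over all synapses); ``sim_fluor`` the simulated
    fluorescence proxy on the target's grid; ``r_rest`` / ``v_rest`` come
    from the settled pre-stimulus state.
    """
    if r_rest is None or v_rest is None:
        raise ValueError("resting state missing")
    missing = set(CONE_BOUNDS) - set(bounds)
    if missing:
        raise ValueError(f"bounds missing components: {sorted(missing)}")
    d_glu = delta_iglusnfr(target, sim_fluor)
    dr, dv = response_deltas(release, v_soma, r_rest, v_rest)
    return DiscrepancyVector(
        iGluSnFR=d_glu,
        RateRest=bounded_penalty(r_rest, bounds["RateRest"]),
        VRest=bounded_penalty(v_rest, bounds["VRest"]),
        RateDelta=bounded_penalty(dr, bounds["RateDelta"]),
        VDelta=bounded_penalty(dv, bounds["VDelta"]),
        VMin=bounded_penalty(float(np.min(v_soma)), bounds["VMin"]),
        VMax=bounded_penalty(float(np.max(v_soma)), bounds["VMax"]),
    )


def peak_time_differences(target: np.ndarray, sim: np.ndarray, dt: float,
                          exclude: Iterable[tuple[float, float]] = (),
                          prominence_frac: float = 0.10,
                          min_separation_s: float = 0.050):
    """Signed timing differences between matched peaks of equal polarity.

    Peaks are local extrema with prominence at least ``prominence_frac`` of
    the trace range and minimum separation ``min_separation_s``.  Every peak
    of the simulated trace is matched to the nearest target peak of the same
    polarity; peaks inside any ``exclude`` window (seconds) are dropped.

    Returns ``(differences_ms, median_ms)``; the median is ``nan`` when no
    peaks match.
    """
    t_arr = np.asarray(target, dtype=float)
    s_arr = np.asarray(sim, dtype=float)
    if t_arr.shape != s_arr.shape:
        raise ValueError("traces must share the grid")
    dist = max(1, int(round(min_separation_s / dt)))

    def peaks(x, sign):
        prom = prominence_frac * (x.max() - x.min())
        idx, _ = find_peaks(sign * x, prominence=prom, distance=dist)
        times = idx * dt
        keep = np.ones(len(times), dtype=bool)
        for (t0, t1) in exclude:
            keep &= ~((times >= t0) & (times <= t1))
        return times[keep]

    diffs = []
    for sign in (+1.0, -1.0):
        pt = peaks(t_arr, sign)
        ps = peaks(s_arr, sign)
        if len(pt) == 0:
            continue
        for tp in ps:
            j = int(np.argmin(np.abs(pt - tp)))
            diffs.append((tp - pt[j]) * 1e3)
    diffs = np.asarray(diffs)
    median = float(np.median(diffs)) if diffs.size else math.nan
    return diffs, median
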