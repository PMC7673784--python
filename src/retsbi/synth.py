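"""Synthetic inputs for the whole pipeline.

Everything the analysis needs is generated programmatically from a seed:

* chirp light stimuli (step + frequency sweep + contrast sweep) with
  optional weak rectification of low intensities;
* stimulus calibration to photon absorption rates (10e3 .. 31e3 P*/s/cone);
* ground-truth model simulations turned into noisy, affinely rescaled
  fluorescence targets (the indicator signal is only defined up to an
  affine transform);
* synthetic sinusoidal electrode recordings through the lumped
  electrode-RC + tissue circuits;
* branched SWC morphologies for the condensation tests;
* end-to-end parameter-recovery experiments.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import discrepancy as dc
from .cable import simulate
from .cells import (BC_TOY_BOUNDS, BC_TOY_TRUTH, bc_light_response,
                    make_bc_toy_cell, make_passive_cell)
from .efield import (RetinaFieldModel, SinusoidFit,
                     parallel_rc_impedance, tissue_impedance)
from .morphology import Morphology, SwcNode
from .sbi import (TruncatedNormalPrior, denormalize_params, normalize_params,
                  run_inference)

__all__ = [
    "ChirpSpec",
    "make_chirp",
    "calibrate_stimulus",
    "align_mean_traces",
    "GroundTruth",
    "generate_target",
    "make_synthetic_electrode_recordings",
    "bc_like_morphology",
    "passive_recovery_experiment",
    "bc_recovery_experiment",
]

PHOTON_RATE_MIN = 10e3   # P*/s/cone at intensity 0
PHOTON_RATE_MAX = 31e3   # P*/s/cone at intensity 1


# ---------------------------------------------------------------------------
# Chirp stimulus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChirpSpec:
    """Segments of the chirp: baseline, bright step, frequency sweep at
    constant contrast, contrast sweep at constant frequency.  Durations in
    seconds; intensities normalised to [0, 1] around ``mean_level``."""

    baseline_s: float = 2.0
    step_s: float = 3.0
    gap_s: float = 2.0
    freq_sweep_s: float = 8.0
    f_start: float = 0.5
    f_end: float = 8.0
    contrast_sweep_s: float = 8.0
    f_contrast: float = 2.0
    tail_s: float = 2.0
    mean_level: float = 0.5
    sample_rate: float = 500.0
    rectify: bool = False

    @property
    def total_s(self) -> float:
        return (self.baseline_s + self.step_s + self.gap_s
                + self.freq_sweep_s + self.gap_s + self.contrast_sweep_s
                + self.tail_s)

    def scaled(self, factor: float) -> "ChirpSpec":
        """Time-compressed copy (all segment durations scaled)."""
        return replace(self, baseline_s=self.baseline_s * factor,
                       step_s=self.step_s * factor,
                       gap_s=self.gap_s * factor,
                       freq_sweep_s=self.freq_sweep_s * factor,
                       contrast_sweep_s=self.contrast_sweep_s * factor,
                       tail_s=self.tail_s * factor)


def make_chirp(spec: ChirpSpec = ChirpSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Normalised chirp intensity trace; returns ``(t, intensity)``."""
    dt = 1.0 / spec.sample_rate
    n = int(round(spec.total_s / dt)) + 1
    t = np.arange(n) * dt
    x = np.full(n, spec.mean_level)

    t0 = spec.baseline_s
    # bright step
    sel = (t >= t0) & (t < t0 + spec.step_s)
    x[sel] = 1.0
    t0 += spec.step_s + spec.gap_s
    if spec.freq_sweep_s > 0:
        # frequency sweep: linearly increasing instantaneous frequency
        sel = (t >= t0) & (t < t0 + spec.freq_sweep_s)
        ts = t[sel] - t0
        k = (spec.f_end - spec.f_start) / spec.freq_sweep_s
        phase = 2 * math.pi * (spec.f_start * ts + 0.5 * k * ts ** 2)
        x[sel] = spec.mean_level * (1.0 + np.sin(phase))
    t0 += spec.freq_sweep_s + spec.gap_s
    if spec.contrast_sweep_s > 0:
        # contrast sweep: amplitude ramp at fixed frequency
        sel = (t >= t0) & (t < t0 + spec.contrast_sweep_s)
        ts = t[sel] - t0
        ramp = ts / spec.contrast_sweep_s
        x[sel] = spec.mean_level * (1.0 + ramp * np.sin(
            2 * math.pi * spec.f_contrast * ts))
    x = np.clip(x, 0.0, 1.0)
    if spec.rectify:
        # weak rectification of intensities below 20% brightness
        low = x < 0.2
        x = x.copy()
        x[low] = 0.2 - 0.8 * (0.2 - x[low])
    return t, x


def calibrate_stimulus(digital: np.ndarray, recorded: np.ndarray | None = None,
                       dt: float | None = None,
                       max_shift_s: float = 0.05):
    """Map a normalised stimulus to photon absorption rates.

    When a recorded trace is given, the digital stimulus is first corrected
    for display timing and amplitude non-linearity: an integer-sample shift
    and a sigmoid amplitude map ``s(x) = 1/(1+exp(-(x-x0)/w))`` (rescaled to
    [0,1]) are fitted by least squares.  The (corrected) intensity is then
    mapped linearly to [10e3, 31e3] P*/s/cone.

    Returns ``(photon_rate, info)``.
    """
    x = np.asarray(digital, float)
    info = {"shift_samples": 0, "sigmoid": None}
    if recorded is not None:
        if dt is None:
            raise ValueError("dt required for timing correction")
        rec = np.asarray(recorded, float)
        if len(rec) != len(x):
            raise ValueError("traces must overlap on a common grid")
        max_shift = int(round(max_shift_s / dt))

        def sig(params, xx):
            x0, w = params
            s = 1.0 / (1.0 + np.exp(-(xx - x0) / w))
            s0 = 1.0 / (1.0 + np.exp(x0 / w))
            s1 = 1.0 / (1.0 + np.exp(-(1 - x0) / w))
            return (s - s0) / (s1 - s0)

        best = None
        for shift in range(0, max_shift + 1):
            xs = np.roll(x, shift)
            xs[:shift] = x[0]
            res = least_squares(lambda p: sig(p, xs) - rec,
                                x0=[0.5, 0.25],
                                bounds=([-1.0, 1e-3], [2.0, 10.0]))
            if best is None or res.cost < best[0]:
                best = (res.cost, shift, res.x, res)
        cost, shift, params, res = best
        if not res.success:
            raise RuntimeError(f"sigmoid fit failed (residual {cost:.3g})")
        xs = np.roll(x, shift)
        xs[:shift] = x[0]
        x = sig(params, xs)
        info = {"shift_samples": shift, "sigmoid": tuple(params),
                "residual": cost}
    rate = PHOTON_RATE_MIN + (PHOTON_RATE_MAX - PHOTON_RATE_MIN) * x
    return rate, info


def align_mean_traces(traces, max_shift: int = 50) -> np.ndarray:
    """Align trace means by integer-sample shift minimising the MSE, then
    average.

    With two traces the second is shifted onto the first; with more, each is
    aligned to the first.  Returns the mean of the aligned traces.
    """
    traces = [np.asarray(tr, float) for tr in traces]
    if len(traces) < 2:
        raise ValueError("need at least two traces")
    ref = traces[0]
    aligned = [ref]
    for tr in traces[1:]:
        best = None
        for s in range(-max_shift, max_shift + 1):
            if s >= 0:
                a, b = ref[s:], tr[: len(tr) - s]
            else:
                a, b = ref[: len(ref) + s], tr[-s:]
            if len(a) == 0:
                continue
            mse = float(np.mean((a - b) ** 2))
            if best is None or mse < best[0]:
                best = (mse, s)
        if best is None:
            raise ValueError("empty overlap after shift")
        s = best[1]
        shifted = np.roll(tr, s)
        if s > 0:
            shifted[:s] = tr[0]
        elif s < 0:
            shifted[s:] = tr[-1]
        aligned.append(shifted)
    return np.mean(aligned, axis=0)


# ---------------------------------------------------------------------------
# Targets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters and noise model of a synthetic target."""

    params: dict
    seed: int
    noise_sd_frac: float = 0.10
    affine_a: float = 0.0
    affine_b: float = 1.0

    def __post_init__(self):
        if self.affine_b <= 0:
            raise ValueError("affine slope must be > 0")


def generate_target(truth: GroundTruth, open_fraction: np.ndarray,
                    dt: float, cell_factory=make_bc_toy_cell):
    """Simulate the ground-truth cell, convolve its release with the
    indicator kernel, rescale affinely and add Gaussian noise.

    Returns ``(target, meta)`` where ``meta`` carries the noiseless
    fluorescence, resting values and the analytic noise floor of the
    affine-invariant distance (noise variance over signal variance).
    """
    cell = cell_factory(**truth.params)
    res = bc_light_response(cell, open_fraction, dt)
    if not res.ok:
        raise RuntimeError(f"ground-truth simulation invalid: {res.status}")
    fluor = dc.iglusnfr_from_release(res.mean_release(), dt)
    rng = np.random.default_rng(truth.seed)
    sd = truth.noise_sd_frac * (fluor.max() - fluor.min())
    target = truth.affine_a + truth.affine_b * fluor \
        + rng.normal(0.0, truth.affine_b * sd, size=fluor.shape)
    sig_var = float(np.sum((fluor - fluor.mean()) ** 2))
    noise_floor = (len(fluor) * sd ** 2) / (sig_var + len(fluor) * sd ** 2)
    meta = {
        "fluor_clean": fluor,
        "v_rest": float(res.vm[cell.soma, 0]),
        "r_rest": float(res.mean_release()[0]),
        "noise_floor": noise_floor,
        "result": res,
    }
    return target, meta


# ---------------------------------------------------------------------------
# Synthetic electrode recordings
# ---------------------------------------------------------------------------


def make_synthetic_electrode_recordings(
        r_el: float, c_el: float, sigma_star: float, eps_star: float,
        seed: int, model: RetinaFieldModel | None = None,
        freqs=(25.0, 40.0), amplitudes_25=(0.2, 0.4),
        noise_frac: float = 0.0, skew: float = 0.0,
        duration_s: float = 0.2, sample_rate: float = 10e3):
    """Sinusoidal currents through the electrode circuits with and without
    retinal tissue.

    For each 25 Hz amplitude a matching 40 Hz stimulus at half the amplitude
    is generated (mirroring the recording protocol).  Returns a dict with
    stimulus specs, time grids and current traces plus the ground truth.
    ``skew`` adds a second-harmonic distortion; ``noise_frac`` additive
    Gaussian noise relative to each trace's amplitude.
    """
    if model is None:
        model = RetinaFieldModel()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sample_rate)
    bath = replace(model, sigma_retina=model.sigma_ames,
                   eps_retina=model.eps_ames)
    out = {"vstims": [], "i_ames": [], "i_retina": [], "t": t,
           "truth": {"re": r_el, "ce": c_el, "sigma": sigma_star,
                     "eps": eps_star}}
    retina = replace(model, sigma_retina=sigma_star, eps_retina=eps_star)
    z_bath = {f: tissue_impedance(bath, f) for f in freqs}
    z_ret = {f: tissue_impedance(retina, f) for f in freqs}
    for amp25 in amplitudes_25:
        for f in freqs:
            amp = amp25 if f == 25.0 else amp25 / 2.0
            v = SinusoidFit(frequency=f, amplitude=amp, phase=0.0)
            z_el = parallel_rc_impedance(r_el, c_el, f)
            for key, z_t in (("i_ames", z_bath[f]), ("i_retina", z_ret[f])):
                ph = v.phasor / (z_el + z_t)
                trace = np.imag(ph * np.exp(1j * 2 * math.pi * f * t))
                if skew:
                    trace = trace + skew * abs(ph) * np.sin(
                        2 * 2 * math.pi * f * t)
                if noise_frac:
                    trace = trace + rng.normal(
                        0.0, noise_frac * abs(ph), size=trace.shape)
                out[key].append(trace)
            out["vstims"].append(v)
    return out


# ---------------------------------------------------------------------------
# SWC fixture
# ---------------------------------------------------------------------------


def bc_like_morphology(seed: int = 0, n_nodes: int = 140) -> Morphology:
    """A branched, BC-like tree: soma, a dendritic tuft and an axon ending
    in a branched terminal system, >= ``n_nodes`` nodes."""
    rng = np.random.default_rng(seed)
    nodes = [SwcNode(1, 1, 0.0, 0.0, 0.0, 4.0, -1)]
    next_id = 2

    def grow(parent_id, structure, direction, n, radius, step=2.0,
             wobble=0.3):
        nonlocal next_id
        pid = parent_id
        by_id = {n.id: n for n in nodes}
        p = by_id[pid]
        pos = np.array([p.x, p.y, p.z])
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        last = pid
        for _ in range(n):
            d2 = d + wobble * rng.normal(size=3)
            d2 = d2 / np.linalg.norm(d2)
            pos = pos + step * d2
            nodes.append(SwcNode(next_id, structure, *pos,
                                 max(radius * (0.9 + 0.2 * rng.random()),
                                     0.2), last))
            last = next_id
            next_id += 1
        return last

    # dendrites: two branches upward
    for ang in (0.4, -0.4):
        grow(1, 3, (math.sin(ang), 0.1, 1.0), n=12, radius=0.6)
    # axon trunk downward
    trunk_end = grow(1, 2, (0.0, 0.0, -1.0), n=30, radius=0.8, wobble=0.1)
    # branched terminal system
    tips = [trunk_end]
    depth = 0
    while len(nodes) < n_nodes:
        new_tips = []
        for tip in tips:
            for ang in (0.7, -0.7):
                e = grow(tip, 2, (math.sin(ang + 0.2 * depth),
                                  math.cos(ang), -0.6),
                         n=8, radius=0.4)
                new_tips.append(e)
        tips = new_tips
        depth += 1
        if depth > 6:
            break
    return Morphology(nodes=nodes, source=f"synthetic-bc-seed{seed}")


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------


def _step_current(n_comp, comp, t, levels):
    """Piecewise-constant injected current: ``levels`` is a list of
    (t_start, amplitude_A)."""
    inj = np.zeros((n_comp, len(t)))
    for (t0, amp) in levels:
        inj[comp, t >= t0] = amp
    return inj


def passive_recovery_experiment(seed: int, rounds: int = 2,
                                n_per_round: int = 200,
                                noise_frac: float = 0.02,
                                epochs: int = 600):
    """Recover (Rm, Cm) of a passive single-compartment cell from a noisy
    voltage response to current steps.

    The summary statistic is the variance-normalised MSE between the
    simulated and target voltage traces (1-dimensional).  Returns a report
    dict with the posterior, coverage flags and contraction diagnostics.
    """
    bounds = np.array([[5e3, 3e4], [0.5, 2.0]])  # Rm (ohm cm^2), Cm (uF/cm^2)
    truth = np.array([1.3e4, 1.18])
    dt = 1e-3
    t = np.arange(0, 0.8 + dt / 2, dt)
    levels = [(0.1, 5e-12), (0.4, 0.0), (0.5, -5e-12), (0.7, 0.0)]

    def simulate_v(rm, cmv):
        cell = make_passive_cell(Rm=rm, Cm=cmv)
        inj = _step_current(1, 0, t, levels)
        res = simulate(cell, dt=dt, t_total=t[-1], i_inj=inj)
        return res.vm[0], res.status

    v_true, _ = simulate_v(*truth)
    rng = np.random.default_rng(seed)
    sd = noise_frac * (v_true.max() - v_true.min())
    target = v_true + rng.normal(0.0, sd, size=v_true.shape)
    t_var = float(np.sum((target - target.mean()) ** 2))

    def simulator(u, sim_seed):
        theta = denormalize_params(u, bounds)
        v, status = simulate_v(*theta)
        if status != "ok":
            return status, np.array([np.inf])
        mse = float(np.sum((target - v) ** 2)) / t_var
        return "ok", np.array([mse])

    prior = TruncatedNormalPrior.unit_box(2)
    posterior, records = run_inference(
        simulator, prior, rounds=rounds, n_per_round=n_per_round, seed=seed,
        hidden=(30, 30), epochs=epochs)

    u_truth = normalize_params(truth, bounds)
    covered = []
    for d in range(2):
        lo, hi = posterior.marginal_interval(d, 0.9, seed=seed)
        covered.append(bool(lo <= u_truth[d] <= hi))
    report = {
        "posterior": posterior,
        "records": records,
        "truth_normalized": u_truth,
        "covered": covered,
        "posterior_var": posterior.marginal_var(seed=seed),
        "prior_var": prior.var(),
        "bounds": bounds,
    }
    return report


def bc_recovery_experiment(seed: int, rounds: int = 3, n_per_round: int = 300,
                           chirp_scale: float = 0.12,
                           dt: float = 4e-4, noise_sd_frac: float = 0.10,
                           epochs: int = 800, hidden=(10,)):
    """Recover the four BC-toy parameters (two conductances, release gain,
    pool size) from a noisy fluorescence target.

    The target is the ground-truth cell's release convolved with the
    indicator kernel, affinely rescaled and noised; summaries are the full
    seven-component discrepancy vector with the OFF-BC penalty bounds.
    """
    names = list(BC_TOY_BOUNDS)
    bounds = np.array([BC_TOY_BOUNDS[k] for k in names], float)
    truth_phys = np.array([BC_TOY_TRUTH[k] for k in names])

    spec = ChirpSpec(sample_rate=1.0 / dt).scaled(chirp_scale)
    _, intensity = make_chirp(spec)
    # kainate drive follows the light; the quadratic map gives the dynamic
    # range needed to swing the terminal through the CaL activation foot
    open_frac = 0.05 + 0.85 * intensity ** 2

    truth = GroundTruth(params=dict(zip(names, truth_phys)), seed=seed,
                        noise_sd_frac=noise_sd_frac, affine_a=1.0,
                        affine_b=2.0)
    target, meta = generate_target(truth, open_frac, dt)
    bounds_tbl = dc.OFF_BC_BOUNDS

    def simulator(u, sim_seed):
        theta = denormalize_params(u, bounds)
        cell = make_bc_toy_cell(**dict(zip(names, theta)))
        res = bc_light_response(cell, open_frac, dt)
        if not res.ok:
            return res.status, np.full(7, np.inf)
        rel = res.mean_release()
        fluor = dc.iglusnfr_from_release(rel, dt)
        vec = dc.discrepancy_vector(
            target, fluor, rel, res.vm[cell.soma],
            r_rest=float(rel[0]), v_rest=float(res.vm[cell.soma, 0]),
            bounds=bounds_tbl)
        return "ok", vec.as_array()

    prior = TruncatedNormalPrior.unit_box(4)
    posterior, records = run_inference(
        simulator, prior, rounds=rounds, n_per_round=n_per_round, seed=seed,
        hidden=hidden, epochs=epochs)

    u_truth = normalize_params(truth_phys, bounds)
    covered = []
    for d in range(4):
        lo, hi = posterior.marginal_interval(d, 0.9, seed=seed)
        covered.append(bool(lo <= u_truth[d] <= hi))
    best_delta1 = min(float(r.summaries[r.valid, 0].min())
                      for r in records)
    report = {
        "posterior": posterior,
        "records": records,
        "truth_normalized": u_truth,
        "covered": covered,
        "posterior_var": posterior.marginal_var(seed=seed),
        "prior_var": prior.var(),
        "best_delta_iglusnfr": best_delta1,
        "noise_floor": meta["noise_floor"],
        "bounds": bounds,
    }
    return report
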