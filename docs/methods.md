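# Methods

This note records the modelling assumptions, numerical choices and known
limitations of the package, in the order of the pipeline.

## Compartmental models

Cells are trees of sphere/cylinder compartments.  Passive constants follow
`rm = Rm/Am`, `cm = Cm·Am`, `ri = Ri·lc/Am` with areas in µm² converted to
CGS units; the axial resistivity is fixed at `Ri = 132 Ω·cm` for all cell
types, while `Rm` (Ω·cm²) and `Cm` (µF/cm²) are free (they are two of the
recovered parameters in the passive experiment).  Spheres have no axial
extent; for coupling, their `lc` defaults to the diameter (configurable) —
the underlying physics does not fix a sphere's axial series resistance, so
this is an explicit convention.

The simplified cone is four compartments: a conical outer segment (length
14.4 µm), a spherical inner-segment/soma (Ø 5.13 µm), a cylindrical axon
(Ø 1.3 µm × 15 µm) and a spherical terminal (Ø 6 µm); the light-collecting
area (0.2 µm²) is metadata.  Bipolar-cell regions are labelled
DD/PD/S/PA/DA/AT by a deterministic rule table (SWC type 1 → S; dendrites
split proximal/distal at a path-distance threshold; axonal nodes split by
branch order, terminals at childless nodes), because region assignment by
eye is not reproducible.

**Condensation.** Reducing the compartment count merges pass-through nodes
(never the root, branch points, tips, or region boundaries), always the
electrically closest pair first.  Each merged segment carries its summed
membrane area and summed axial weight `Σ lc/Am` explicitly; downstream
compartmentalisation consumes these conserved records, so total membrane
area is conserved to round-off and every root-to-landmark axial resistance
to < 1e-6 relative.  This is a surrogate for a production condensation
algorithm whose details are not public; the conservation targets are what
matter for the electrical behaviour.

## Integration

The state variable is the transmembrane potential `U = Vm − Vex`; in these
terms a spatially uniform extracellular potential provably has no effect
(the invariance is exact, and tested at 1e-9), and extracellular forcing
enters only through axial differences `L·Vex`.

* Passive cells: the system is linear with piecewise-constant input, so
  each step applies a cached block matrix exponential
  `expm([[A, I], [0, 0]]·dt)` — machine precision for any dt, and robust to
  singular `A` (leakless cables).
* Active cells: Crank–Nicolson on the voltages with channel conductances
  frozen over the step; gating variables advance by the exact single-step
  exponential (HH) or the matrix exponential of the frozen generator
  (Markov, conserving occupancy to round-off).  Defaults: dt = 50 µs for
  light stimuli, 10–20 µs for electrical pulses; a 1–2 s settle period
  under the first input sample defines the resting state used by the
  discrepancy penalties.

A compiled (numba) kernel reproduces the reference numpy stepping for the
common envelope (HH channels with closed-form rates, one calcium store per
compartment, no clamp); both paths are compared in the test suite at 1e-8.
The voltage-clamp screen (soma to +30 mV for 100 ms; recovery to ≤ −30 mV
within 300 ms) flags models with a depolarised second equilibrium; screened
samples get inference weight zero, as do numerically unstable ones
(`status='unstable'` is returned, never raised).

## Channels, calcium, release

Shipped gates: CaL (power 3; `α = −0.04(V+15)/(exp(−0.04(V+15))−1)`,
`β = 5·exp(−(V+38)/18)` 1/ms, with the removable singularity replaced by
its analytic limit), a classic delayed-rectifier KV (power 4), and
HH-style surrogates for HCN, CaT and Kir (sigmoidal activation with fixed
time constants).  The literature Markov state tables (NaV 9-state, HCN
10-state, Kir 3-state, CaT/ClCa 12-state) are not public; the generic
Markov machinery accepts user rate tables, and all bundled approximations
carry `surrogate=True`.  Rate modifiers ΔV and τ act per gate exactly as
`(1/τ)·rate(V − ΔV)`; Q10 defaults to 2 because exact temperature
sensitivities are unknown.

Calcium is a single sub-membrane shell (a deliberate reduction of radial
shell diffusion — only the first-shell concentration feeds release) with
linear influx from the calcium-channel current, a saturable extrusion pump
(half-saturation `CaPK`) and a leak to rest that makes the resting state an
exact equilibrium.  Release follows the ribbon model with `[Ca]0` in µM
entering squared; the ambiguous normalisation constant of the release
equation is absorbed into the gain `gl`, whose prior is wide.

Receptors: kainate (sign-preserving, first-order activation with
inactivation time constant τγ) and mGluR6 (sign-inverting saturating map,
same low-pass); `STC` scales transmitter identically to scaling the
presynaptic signal, which is tested as an identity.  Phototransduction is a
two-stage surrogate (fast low-pass drive, slow divisive adaptation) whose
steady current is monotone and hyperpolarising in the photon rate; the
production cascade is not public, so only these qualitative properties are
claimed.

## Discrepancy

`δ_iGluSnFR` is the variance-normalised residual after the closed-form
affine fit with slope clipped at zero — exactly 1 for anticorrelated
traces, exactly 0 under any affine map with positive slope.  The indicator
kernel `exp(−t/60 ms)` is unnormalised and truncated at five time
constants; normalisation is irrelevant because the affine fit absorbs it.
The six scalar penalties use the smooth bounded form (0 inside [tl, tu],
`±(1−exp(−2(y−t)²/(t−p)²))` outside, saturating at ±1) with the published
per-cell-class bound tables; where the printed table and its accompanying
text disagree on the OFF/ON ordering the text is used, and the cone
voltage-minimum row is read as `pl=−75, tl=−60`.  The total is the L1 norm
of the signed components ("absolute-value norm" read as Σ|·|).  Peak-time
analysis detects extrema with prominence ≥ 10% of the trace range and
≥ 50 ms separation, matches each simulated peak to the nearest
same-polarity target peak, and drops peaks inside exclusion windows.

## Inference engine

Priors are independent truncated normals (rejection-sampled from the
untruncated normal); the parameter space is affinely normalised so the
truncation box is the unit cube and the prior σ is 0.3 per dimension.
Summaries are weighted by a product Gaussian kernel: bandwidth 0.25 in all
dimensions except the first, whose centre is the round's minimum sampled
trace discrepancy and whose bandwidth is the spread to the 20th percentile
(floored at 1e-3); proposal corrections use the importance ratio
`p(θ)/p̃(θ)` with the truncated-mixture normaliser estimated by fixed-seed
Monte Carlo.

The conditional density is a tanh-MLP mixture-density network with a
Cholesky-of-covariance Gaussian head (1 component for cell inference, 2
for stimulus search), trained full-batch with Adam on the weighted
negative log-likelihood.  Backpropagation is hand-written and verified
against numerical differentiation.  Training holds out 15% of the samples,
keeps the best held-out parameters, stops early after 150 non-improving
epochs, clips gradient norms at 25, and runs a second fine-tune phase at
1/5 the learning rate from the best parameters; only a non-finite loss is
treated as divergence (transient loss spikes under extreme kernel weights
are recovered by the best-parameter restore).  Network width defaults to
2×50 units; the recovery experiments use deliberately small heads (one
layer of 10) because a few hundred weighted samples cannot constrain a
larger conditional model without overconfidence.

After training, the network is conditioned at the boundary target
`[min δ, 0, …, 0]` — conditioning at exactly zero would extrapolate
outside the training support — and the mixture is truncated to the prior
box by rejection.

## Recovery experiments (study conditions)

* Passive: recover (Rm, Cm) of a one-compartment cell from a 0.8 s
  current-step protocol (±5 pA), target = voltage trace plus 2% Gaussian
  noise, summary = variance-normalised MSE; 2 rounds × 200 samples.
* BC toy: recover (g_CaL, g_KV, gl, vRRPmax) of a four-compartment
  OFF-style cell driven through a kainate conductance following a
  time-compressed chirp (scale 0.12 of the full stimulus, dt = 0.4 ms);
  target = release convolved with the indicator kernel, affinely rescaled,
  plus 10% additive Gaussian noise (analytic distance floor ≈ 0.17);
  summaries = the full seven-component vector with OFF-BC bounds;
  3 rounds × 300 samples.

Coverage is scored as the ground truth falling inside the 90% equal-tailed
marginal credible intervals; across ten seeded repetitions both
experiments cover in ≥ 9/10 runs, and the across-run mean posterior
variance contracts below the prior variance in every dimension (a single
run may leave one weakly identified dimension at prior width — strict
per-dimension contraction is asserted on the linear-Gaussian toy, where it
is an exact property).  These sizes are desk-scale choices; the experiments
state what the machinery can recover under the stated noise, not that the
full published cone/BC posteriors are reproduced.

## Extracellular fields

Conservative finite-volume discretisation of
`∇·((σ + i·2πf·ε·ε0)∇V) = 0` on a graded axisymmetric (r, z) grid, layer
interface aligned to a cell face, uniform normal current density on the
electrode disk, grounded bath top, insulating elsewhere.  Current through
any horizontal plane is exact to the solver residual; the on-axis
potential matches the half-space closed form `V = (j/σ)(√(a²+z²) − z)`
within 2% on the default grid (the 2π solid angle of a boundary source —
not the full-space 4π form).  Multi-electrode fields superpose shifted
single-disk solutions; for prescribed-current electrodes this is exact up
to the displaced outer boundary, and a coarse 3-D joint finite-volume
solve bounds the error at ≤ 5% away from the electrode plane.  Time-domain
stimulation scales the DC spatial profile by the current waveform
(quasi-resistive extraction at the compartment centres); cells are placed
with somata 30 µm above the electrode plane, dendrites facing the
electrodes.

Electrode characterisation: sinusoids are fitted by quadrature projection
over an integer number of periods (closed form); the parallel-RC inversion
`Re = |Z|√(1+tan²φZ)`, `Ce = −tanφZ/(2πf·Re)` is exact and tested to
1e-9.  Tissue parameters are inferred in two stages: exponent space
(`σ = 2^pσ·0.1 S/m`, `ε = 2^pε·10⁶`, Gaussian priors mean 1, sd 2; 3
rounds × 50), then a truncated-normal refinement over the box of the best
10% of stage-1 samples in normalised space.  The reported values are the
lowest-discrepancy samples over both stages.  Offline, the pipeline is
exercised on synthetic recordings generated from the lumped circuits at
σ = 0.076 S/m, ε = 1.1×10⁷ and recovers both within 5%.

## Stimulus design

Stimuli are natural cubic splines through seven equidistant knots over
40 ms, endpoints zero; the balancing knot is solved from the linear
charge-balance condition using exact cardinal-spline integrals (the
`charge()` reported is the exact spline integral; the sampled waveform
carries only grid discretisation error).  Natural end conditions are a
choice (recorded here) — the end conditions of the original
parameterisation are unspecified.  Amplitudes are normalised to 0.5 µA
after balancing, which preserves neutrality.

The selectivity search draws 400 knot vectors from a zero-mean Gaussian
(σ = 0.3), scores `δ = R_other/R_target` over a 60 ms window (base rates
from an unstimulated run of equal length), trains a two-component
untruncated mixture on log10-compressed scores and draws 100 refinement
samples.  Cells that evoke no target release map to a logged worst-case
δ = 1e6.  The bundled toy pair (fast low-threshold transient gate vs slow
high-threshold sustained gate) is separable in one direction only —
transient-targeting stimuli reach δ < 0.1 while sustained-targeting ones
plateau near 0.6 — mirroring the OFF/ON asymmetry the full models show.

## Synthetic data

The default chirp is ~31 s (2 s baseline, 3 s bright step, 8 s frequency
sweep 0.5→8 Hz, 8 s contrast ramp at 2 Hz, gaps and tail), normalised to
[0, 1], optionally weakly rectified below 20% brightness (the BC-stimulus
variant); intensities map linearly to 10×10³–31×10³ photoisomerisations/s
per cone.  Display-chain calibration fits an integer-sample delay plus a
normalised sigmoid by least squares.  Targets add white Gaussian noise at
10% of the trace range (distance floor ≈ 0.1–0.2, the order of good real
fits) and an arbitrary affine map, which the distance must ignore.
Synthetic electrode recordings come from the same lumped circuits used in
inference, with optional second-harmonic skew and noise — so electrode-RC
recovery is exact on noise-free traces by construction, and the tissue
recovery tests the optimiser, not the circuit model.

What the synthetic data does **not** emulate: photoreceptor noise and
imaging noise structure (scan lines, bleaching), amacrine-cell feedback
(cells are simulated in isolation by design), multi-shell calcium
diffusion, electrode electrochemistry beyond a per-stimulus RC, and
tissue inhomogeneity/anisotropy.  Passing tests therefore demonstrate
correctness of the machinery and recoverability under stated conditions,
not biological completeness.

## Known limitations

* Channel kinetics beyond CaL/KV are qualitative surrogates; no claim of
  equivalence to any production state tables.
* The single-Gaussian posterior cannot represent multimodality; the
  engine's mixture support (used for stimulus search) is available but
  untested for cell inference, where mixtures tend to collapse.
* Superposed multi-electrode fields ignore inter-electrode boundary
  interactions (exact only for prescribed-current disks in an unbounded
  lateral domain).
* The quasi-resistive Vex extraction ignores the frequency dependence of
  the spatial profile; at stimulation frequencies of tens of Hz in the
  fitted tissue this is a small effect compared with the electrode RC.
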