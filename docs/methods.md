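# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `perivasc`, in the spirit of a model-description
appendix.

## Physical model

**Geometry.** The perivascular space (PVS) is the annulus between a
vessel of time-dependent radius `R_v(t)` (uniform along the vessel) and
a fixed outer endfoot-tube radius `R_ast`, of axial length `L = 600 µm`.
`y = 0` is the brain-surface entrance (reference pressure 0), `y = L`
the closed deep end (no flow). Both walls are impermeable.

**Area law.** The free cross-section follows
`A_pvs(t) = ⟨A⟩(1 + ⟨a⟩/2·cos(2πt/⟨p⟩)) − A_SMC`, with the medians
`⟨A⟩, ⟨a⟩, ⟨p⟩` taken per (vessel, sleep state, frequency band) from the
episode summaries. `⟨a⟩` is dimensionless (relative peak-to-trough
amplitude of the area oscillation); absolute episode amplitudes are
divided by the episode's median area before aggregation so the law is
dimensionally consistent. `A_SMC = α·⟨A⟩_baseline` lumps smooth muscle
and other flow-obstructing constituents as an incompressible annular
layer against the vessel wall, so the free annulus runs from
`R_v' = sqrt(R_ast² − A_pvs/π)` to `R_ast`; α ∈ {0, 0.25, 0.5} are the
standard scenarios, and the baseline defaults to `⟨A⟩` itself when no
quiet-wakefulness baseline is supplied.

**Flow.** With gap thickness h ≤ 10 µm, frequencies ≤ 15 Hz and
velocities ≤ 200 µm/s, the Womersley number is ≤ 0.1 and the Reynolds
number ≤ 3×10⁻³ (`dimensionless_numbers` reproduces both estimates), so
inertia is negligible and the flow is quasi-steady Stokes. Because the
deformation is axially uniform, continuity gives the volume flux
exactly, `Q(y,t) = (L−y)·dA/dt`, and at each instant the axial profile
is classical annular Poiseuille between `R_v(t)` and `R_ast`:

* mean velocity `u_mean = Q/A`;
* peak velocity `u_peak = max |u_mean| · s(R_v/R_ast)` where `s` is the
  analytic peak/mean shape factor of the annular profile (`u_peak` is a
  pointwise maximum over the profile, attained at the entrance);
* pressure from the annular conductance
  `M = R_ast⁴ − R_v⁴ − (R_ast² − R_v²)²/ln(R_ast/R_v)`,
  `dp/dy = −8µQ/(πM)`, integrated from `p(0) = 0`.

This reduced (lubrication) solution is the primary solver; mass
conservation `∂A/∂t + ∂(A·u_mean)/∂y = 0` holds to round-off and is
asserted at 10⁻⁶ relative in the tests. The thin-gap limit of the
conductance agrees with the plane-Poiseuille `h³` law to < 2 %, and the
conductance factor itself is verified against direct quadrature of the
profile to < 0.1 %.

**Fluid constants.** CSF is water at 35 °C: µ = 6.93×10⁻⁴ Pa·s
(default), with the rounded 7×10⁻⁴ Pa·s exposed for the dimensionless
estimates; ρ = 1000 kg/m³ enters only those estimates.

**Solutes.** 70 kDa dextran uses D = 17 µm²/s, the value obtained from
an apparent neuropil diffusivity of 0.84×10⁻⁷ cm²/s at tortuosity 2 as
adopted in the perivascular-transport literature. For 2000 kDa dextran
the literature value printed alongside it (68 µm²/s) is registered as
the default, although it exceeds the 70 kDa value, which is physically
inverted for a larger molecule; a `2000kda-alt` entry with 6.8 µm²/s is
provided, and neither is asserted as correct.

## Transport solver

The tracer concentration `c(y, r, t)` is advanced on the annulus with
the annular-Poiseuille axial velocity and full molecular diffusion;
radial diffusion is retained because its interplay with radial shear is
what produces oscillatory (Taylor-type) dispersion. Radial advection
from wall motion is neglected — justified by Wo ≪ 1 and the small
relative wall excursions — though the radial grid itself follows the
moving wall (nodes at fixed normalized positions across the gap), which
reintroduces a first-order surrogate of that advection at no cost.

Discretization: operator splitting per time step (axial step, then
radial step), with

* axial: central differences; diffusion backward Euler, advection
  trapezoidal (Crank–Nicolson weight 0.5). A fully implicit advection
  step would add numerical axial diffusion `u²Δt/2`, which at the
  default Δt = 5 ms is a few percent of D and would bias the fitted
  dispersion; the trapezoidal weight cancels it while every substep
  stays unconditionally stable.
* radial: conservative finite-volume form of the cylindrical operator,
  backward Euler, same matrix for all axial positions (the geometry is
  axially uniform).
* grids: axial spacing ≤ 1 µm, time step ≤ 5 ms, ≥ 8 radial cells
  across the gap (defaults 1 µm, 5 ms, 12 cells). Halving Δt and both
  cell sizes moves D_eff by < 2 % on the reference case.

With zero flow the solver collapses to a single radial row and
prefactorizable 1-D diffusion; the discrete variance of a Gaussian pulse
then grows as 2Dt to < 1 %, and tracer mass under no-flux boundaries is
conserved to 10⁻⁶ relative (exactly conservative regimes: zero flow, or
axially uniform velocity, where central advection telescopes).

**Oscillation phase for transport runs.** The area law is started at
the *median* area (cosine shifted by −π/2) rather than at the maximum.
The tracer column breathes axially with the PVS — its material extent
scales as 1/A(t) — so variances sampled at an arbitrary phase carry a
reversible modulation of order ⟨a⟩ that is not dispersion. Starting at
the median phase and evaluating dispersion at a whole number of
oscillation cycles (the last completed cycle within the nominal 40 s
window) cancels this modulation to O(⟨a⟩²/8), leaving the genuine,
non-negative shear-dispersion signal. The flow solver itself keeps the
plain cosine law; only transport sampling is phase-aligned.

**Dispersion analysis.** Initial Gaussian pulse of σ₀ = 2 µm at L/2
(equivalent to a point source released at t = −σ₀²/2D); `D_eff` is the
least-squares fit of the 1-D pure-diffusion profile to the
section-averaged concentration at the evaluation time, cross-checked
against the moment estimator `(σ²(T) − σ₀²)/2T`; a discrepancy above 2 %
warns and the fit is reported. A run is rejected if 6σ of the final
pulse would touch the domain ends. The steady-flow limit of the solver
agrees with the closed-form annular Taylor–Aris coefficient (computed
independently by quadrature of the radial cell problem) to within 10 %.

**Influx analysis.** Concentration 0 initially, held at 1 at the
entrance at all times (also during outflow phases — an accepted
convention of this problem class); the front is the deepest axial
position where the section-averaged concentration reaches 0.1, localized
by sub-cell interpolation. With oscillatory flow the raw front sweeps
back and forth with the fluid excursion, so the reported trajectory and
time-to-depth are computed from a centered moving average spanning
exactly one oscillation period (the unsupported half-windows at the ends
are trimmed); the smoothed front is non-decreasing. A front that never
reaches the requested depth within the horizon is reported as censored.

**Cardiac scenarios.** For target peak velocities of 10/50/100 µm/s at a
cardiac period (default 0.125 s ≈ 8 Hz murine heart rate; admissible
range is the cardiac band 1/15–1/4 s with 20 % slack), the relative area
amplitude is calibrated by bracketed root finding on the analytic peak
velocity (tolerance well under 1 %), then dispersion/influx are run with
the calibrated model.

**Obstruction and enhancement.** Peak velocity is strictly increasing in
α for any geometry (the flux divides by a smaller free area). Dispersion
enhancement is not, in this model class, universally monotone in α at
vasomotion frequencies: thinning the free gap raises velocities (∝1/A)
but lowers the shear-dispersion coefficient (∝h² at fixed `u·h`), and a
small-amplitude analysis of the radial cell problem shows the two nearly
cancel, with a shallow dip at α = 0.25 for slow (VLF/LF) forcing. At
cardiac frequency the finite-frequency suppression of dispersion
(ωτ_radial ≳ 1) is relieved as the gap thins, and enhancement rises
strictly with α; the monotonicity property is therefore verified on a
cardiac-period reference vessel. At large relative amplitudes (as in the
obstructed scenarios' effective amplitudes) the velocity bursts near the
area trough strengthen the increase further.

## Signal chain

* Savitzky–Golay smoothing: 0.1 s window (nearest odd sample count),
  polynomial order 3; exact on cubics.
* Band decomposition: zero-phase (forward–backward) order-3 Butterworth
  filters per band; the continuous band is the 0.1 Hz low-pass.
  Zero-phase filtering is used so oscillation-event times are not
  lagged. Respiratory/cardiac amplitudes of endfoot and PVS are
  computed but flagged unreliable (below the optical resolution of the
  recordings the pipeline emulates).
* Oscillation events: alternating local extrema (of two same-kind
  neighbours the more extreme survives); peak-to-trough amplitude per
  trough→peak pair, peak-to-peak period between consecutive maxima. The
  detector agrees exactly with an independent brute-force scan.
* QC: Pearson correlation between the two edge-position series of a
  structure (rigid tissue motion moves both edges together); inclusive
  thresholds 0.8 (lumen) and 0.7 (endfoot). Failing traces are excluded,
  never imputed.
* Sleep scoring: 1 s epochs; band powers delta 0.5–4, theta 5–9, sigma
  9–16 Hz from zero-phase filters; EMG RMS threshold (adaptive geometric
  mean of the 10th/99th epoch percentiles — the 99th because sleep-heavy
  recordings leave wake only in the far upper tail — or a fixed value).
  Rules: high EMG → wake; low EMG with sigma elevated and delta reduced
  against a causal running NREM baseline → IS; low EMG with theta/delta
  > 0.5 *and* reduced delta → REM (the delta condition encodes
  "low-amplitude theta activity" and rejects single-epoch ratio noise
  inside NREM); otherwise NREM. Wake runs of 1–10 s inside NREM/IS with
  an ECoG total-power drop become microarousals (single-epoch candidates
  must be EMG-active in both half-epochs, so sub-second bursts are not
  scored). Wake is relabelled contextually: before NREM → WBS, the 10 s
  after REM → WAS — matching how those states are defined behaviourally.
* Episode aggregation: mean of event statistics within an episode,
  median across episodes per (vessel, state, band); relative area
  amplitudes divide by the episode's median area; states with no
  contributing episodes are absent, not zero-filled. PVS area is
  `π/4·(endfoot² − lumen²)`.

## Linescan extraction

Stacks are block-averaged toward 100 Hz and 20 samples/µm (integer
factors minimizing the deviation, ties toward the smaller factor — e.g.
250 Hz → factor 3, 333 Hz → factor 3). Thresholds are (time, value)
control points linearly interpolated across the scan with constant
extrapolation; the automated default estimates, per window, background
as the median below an initial percentile split and foreground as a
quantile of the above-split values (75th for the red lumen channel, 90th
for the green channel whose thin bands are mostly flank samples), then
takes the midpoint. Edges are the outermost threshold crossings,
localized by linear interpolation between the bracketing samples; frames
with no crossing are flagged missing and excluded downstream, never
interpolated. When more than two green bands appear, the outermost
crossings still define the endfoot tube — a stated convention, not a
derived rule. PVS width is endfoot minus lumen diameter (total and
per-side); negative values are retained but flagged.

## Synthetic data

The generators provide the statistical structure the analysis assumes,
not a fit to any deposited dataset:

* Hypnograms: cycles WBS (15 s) → NREM (180 s) → IS (30 s) → REM (60 s)
  → WAS (10 s), with Poisson microarousals (durations uniform in
  [1, 10) s, ≥ 2 s of host state between events) inside NREM/IS.
* Diameters: per-state medians plus state-gated constant-amplitude
  sinusoids with uniformly random phase per episode, exponential ramps
  (τ = 2 s) at state transitions, Gaussian measurement noise, and a
  shared rigid-drift random walk that moves both edges of a structure
  (so the QC correlation filter is meaningfully testable). Defaults:
  ~19/27.5 µm lumen/endfoot in NREM, REM dilation ×1.2 with the endfoot
  following only partially (PVS shrinks), arousal constriction with PVS
  enlargement, VLF/LF relative amplitudes largest in NREM/IS (0.10/0.06
  of the median), small respiratory/cardiac components. All values are
  plausible placeholders stored in one editable YAML profile; they are
  not measured values.
* Linescans: red channel a boxcar of the lumen diameter, green channel
  two bands whose outer edges span the endfoot diameter, Gaussian PSF,
  additive noise, embedded ground truth.
* ECoG/EMG: band-limited noise carriers amplitude-modulated per state
  (NREM delta-dominant; IS sigma/theta-elevated with reduced delta; REM
  theta-dominant with theta/delta power ratio > 0.5 and the lowest EMG;
  wake broadband with high EMG; microarousals with reduced total ECoG
  power and high EMG).

What passing round-trip tests show — and what they do not: the chain
recovers known band amplitudes within 10 %, periods within 5 %, scores
synthetic sleep at ≥ 95 %, and extracts diameters to within one spatial
sample at SNR ≥ 10. Real recordings add slow focus drift, non-sinusoidal
and amplitude-modulated vasomotion, state-transition ambiguity and
segmentation artifacts that the generators deliberately do not emulate;
performance on deposited data is bounded, not guaranteed, by these
results.

## Known limitations

* The reduced solver assumes axially uniform deformation; no peristaltic
  wave propagation, no net (rectified) pumping mechanism, no poroelastic
  wall. A full moving-mesh FEM cross-check is not included; the
  closed-form oracles above stand in for it.
* Enhancement values at the default Δt carry a residual O(Δt) splitting
  error of a few tenths of a percentage point; tests that probe scaling
  laws use the moment estimator, which is discretely exact for variance
  growth.
* The entrance Dirichlet condition feeds tracer during outflow phases;
  influx times therefore bound the no-source case from below.
* Sleep scoring assumes the recording contains some wake when the
  adaptive EMG threshold is used; pass a fixed `emg_threshold` for
  all-sleep segments.

## Problem sizes

Default analyses run on a 601-node axial grid with 12 radial cells and
5 ms steps (40 s dispersion window ≈ 8×10³ steps). The test suite and
the acceptance script use these sizes or smaller (shorter horizons,
L = 300–400 µm reference domains) — chosen so the full suite runs on a
laptop-class single core in a few minutes while staying inside the
regime the convergence test validates.
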