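# Methods

This note records the models behind `thrombovol`, the parameters that matter,
the numerical choices, and what the synthetic fixtures do and do not emulate.

## Optical thresholding

A z-stack is an ordered list of 8-bit planes, focal (adhesion) plane first,
spaced `Δz` (default 0.5 µm) with pixel pitch `f` (default 0.33 µm/px, so a
512 × 512 sensor images 28 547.48 µm²). For threshold `Thr`, plane *i*
contributes area `A_i = #{pixels ≥ Thr} · f²` and the stack volume is
`V_OT = Δz Σ_{i=1..N} A_i`. The stack height is `H = (N−1)·Δz`; note the
volume sum spans N slabs of Δz while the height spans N−1 steps — both
definitions are kept as conventionally stated, and the one-slab discrepancy
is far below the method's uncertainty.

**Threshold selection.** Both `V_OT(Thr)` and the maximum height
`H_max(Thr)` (index of the topmost plane with any surviving pixel, times Δz)
are non-increasing survival curves. Coming down from high thresholds,
`H_max` saturates at the stack height while `V_OT` turns through an elbow.
The selection rule is made explicit and parameter-free: **the largest
threshold at which `H_max` attains its maximum over thresholds ≥ 1**
(threshold 0 is excluded because every pixel trivially survives). Ties break
toward the larger threshold; a height curve that is identically zero above
threshold 0 is a degenerate stack and raises. On real-like stacks whose
upper planes contain only the background noise floor, the selected threshold
lands just above that floor (~30 on the default 0–255 fixtures), which is
the regime where the rule is informative.

**Uncertainty.** The stepwise threshold curves justify a threshold
identification error of δThr = 3 units; treating it as uniform gives
`u(Thr) = δThr/√3`, and `u(V_OT) = |dV/dThr| · u(Thr)`, reported as a
fraction of `V_OT(Thr)`. The slope is a central finite difference on the
integer threshold grid (one-sided at the ends). The magnitude of `u(V_OT)`
is a property of the intensity histogram near the selected threshold: on
high-contrast stacks (object ≈ 200, floor ≈ 8) the volume curve is flat at
the selection point and u is small (≲ 1 %); on low-contrast stacks whose
object intensities sit one to two noise standard deviations above the
selected threshold, u is 10–25 % — the regime real stacks with dim aggregate
tips show, and the regime the low-contrast test fixture (object 35, sd 4)
reproduces.

**Sensitivity analysis.** `ΔV_OT(Thr+i) = 100·(V(Thr+i) − V(Thr))/V(Thr)`
for offsets i ∈ [−10, 10]; it inherits monotonicity from the volume curve
and is exactly 0 at i = 0.

## Conduction forward model

The flow channel (500 × 100 µm section; modeled streamwise length 840 µm =
the 280 µm electrode window plus one window-width up- and downstream, with
insulating ends — current crowding near coplanar electrodes decays over the
track/gap scale, so farther truncation is immaterial) is discretized on a
tensor-product voxel grid. The conduction problem ∇·(σ∇φ) = 0 is assembled
as a 7-point finite-volume stencil with series (harmonic-mean) face
conductances `G = A / (d₁/2σ₁ + d₂/2σ₂)`; electrode footprints on the bottom
wall couple wall-adjacent cells to fixed potentials ±V/2 (drive 100 mV)
through their half-cell conductance, all other boundaries are zero-flux.
`|Z| = V/I` with I the total current through one electrode; the treatment is
purely resistive because at the 150 kHz working frequency platelet membranes
act as insulators and only the magnitude is used.

**Electrodes.** Two nested u-shaped footprints inside the 280 × 280 µm
window: the outer U (30 µm track) opens +y, the inner U (20 µm track,
default 70 µm clearance) opens −y. Arm lengths beyond the track widths and
window size are configuration, not measured facts.

**Grid.** Default: 10 µm cells in x,y over the window (28 × 28), geometric
coarsening into the extensions, 2 µm z-layers near the wall growing by 1.5×
to the roof (~17 k unknowns). 10 µm is chosen commensurate with the 30/20 µm
track widths so the electrode masks rasterize exactly and remain aligned
under halving; misaligned grids (8 µm, 4 µm) perturb the effective track
width by ±2 µm and dominate the discretization error. Systems ≤ 4000
unknowns are solved by direct sparse LU; larger ones by Jacobi-preconditioned
conjugate gradients at relative tolerance 1e-10 (the derived |Z| then agrees
with the direct solve to ~1e-10).

**Partial-volume interface voxels.** The voxel straddling the thrombus
surface carries the series (harmonic) mixture of thrombus and blood over its
fractional fill; bulk voxels are two-phase. The series mix is the physically
right combination for the dominant vertical throttling through a thin
surface layer, and it makes |Z|(k) continuous and *strictly* increasing in
the height scale factor — the property the inversion relies on. A strictly
binary voxel assignment would make |Z|(k) piecewise constant and the
inversion residual would floor at the staircase step.

**Cell constant.** `K = |Z|·σ` for a uniform medium is geometry-only. The
current density diverges at the coplanar electrode edges, so the raw
discrete K converges only first-order in the voxel size (measured ≈ −6 %
then −3 % per aligned halving); `cell_constant(…, extrapolate=True)` applies
one Richardson step, `2K(h/2) − K(h)`, which is stable under further halving
at the percent level. Blood conductivity is estimated from the thrombus-free
baseline as `σ_blood = K / Z_baseline` (reference value 0.59 S/m), and the
effective thrombus conductivity is one eighth of it (0.07 S/m): a thrombus
is a platelet agglomerate with conductive plasma-filled interstices, and the
1/8 ratio is the effective-medium value that best reconciles the optical and
impedance volumes.

The height map `h = k·I` is block-averaged onto the grid by exact
area-weighted overlap integrals (the height field is piecewise constant on
pixels; pixels outside the imaged region are bare wall). The imaged field
(512 px · 0.33 µm = 168.96 µm square) is centered in the 280 µm electrode
window. Heights are clamped at the channel roof.

## Scale-factor inversion

`k` is recovered by bisection on [0, k_max], `k_max = h/max(1, I_max)` (the
brightest pixel at the roof), guaranteed by strict monotonicity. Iteration
stops when the bracket satisfies `(hi − lo) ≤ 1e-3·k` (which bounds both the
scale factor error and, through the slope, the impedance residual), with a
60-iteration cap. Measured impedance below baseline beyond a 2 % noise
allowance signals "no physical solution" (detachment or artifact); above the
roof-saturated ceiling it signals an occlusive thrombus and reports k_max.
Saturated (255) pixels trigger a warning since intensity–height linearity is
broken there. `V_IM = f² Σ min(k·I, h)` carries the method's 10 % relative
uncertainty; V_OT carries 15 %. Two estimates are metrologically compatible
when `|V_OT − V_IM| ≤ 2·√((0.15·V_OT)² + (0.10·V_IM)²)` (coverage factor 2).
The 3D reconstruction extrudes each pixel into a rectangular column, so the
enclosed mesh volume equals V_IM exactly; the mesh is watertight whenever
the occupied support has no purely diagonal contacts.

## Perfusion monitoring

`ΔZ(t) = 100·(|Z|(t) − Z₀)/Z₀`, Z₀ the first sample (or a windowed mean for
noisy logs). Groups are keyed on the final ΔZ at 300 s — G1 < 10 %,
G2 [10, 20) %, G3 [20, 40) %, G4 ≥ 40 % — because the bands partition the
axis while crossing times do not; the 10 %-crossing bound (G2 ≤ 240 s,
G3 ≤ 180 s, G4 ≤ 120 s) is a consistency flag, never a rejection. Bands are
half-open with the boundary going to the higher group. The early-decision
rule inverts the bounds: crossing by 120 s predicts G4, by 180 s G3, by
240 s G2; no crossing by 240 s leaves {G1, G2} until the final value.

A detachment event is a maximal interval `[t1, t2]` with `t2 − t1 ≤ 10 s`
over which ΔZ is monotone decreasing up to a 0.2-point-per-step tolerance,
falls by ≥ 5 points in total, and both the first and last steps are genuine
falls (< −0.2) — the boundary condition pins the reported endpoints to the
actual fall rather than letting flat noise floors stretch them. Thresholds
are configurable; the defaults capture a 6-second, ~8-point embolization
transient.

## Synthetic fixtures

Generators are deterministic in their seed and record exact ground truth.

- **Height fields**: pyramids, square frusta and paraboloid domes with
  closed-form volumes, placed on a jittered grid (one shape per grid cell,
  which guarantees disjoint footprints even at ~50 % coverage where
  rejection sampling jams). An optional mural adhesion **carpet** — a
  smoothed 1–3 µm layer — models the platelet film that coats a
  collagen-coated wall before discrete aggregates tower. The carpet matters
  electrically: without it the exposed electrode area shunts the current and
  |Z| is nearly insensitive to aggregate height (log-sensitivity ~0.1);
  with it, all current is throttled through the thrombus layer and the
  inversion becomes well conditioned.
- **Z-stacks**: plane *i* shows object intensity (default 200) plus Gaussian
  signal noise wherever `h > i·Δz`, background noise (mean 8, sd 5)
  elsewhere, clipped to 8 bits; a few pure-background margin planes sit
  above the tips, as acquisition always overshoots the tallest aggregate.
  The margin planes are what make the automatic threshold land just above
  the noise floor instead of at the object intensity. The recorded
  `rendered_volume` (voxelized onto the z-grid) is what thresholding
  recovers exactly in the noiseless limit; it exceeds the analytic volume by
  up to half a slab per covered pixel.
- **Projection images**: `I = round(h/k_true)` clipped at 255, with a
  saturation warning.
- **Traces**: logistic ΔZ rises pinned to ΔZ(0) = 0, the target final value,
  and the target 10 %-crossing time (logistic midpoint solved by Brent's
  method; time constant 25 s), plus Gaussian noise (default sd 0.5 points)
  and optional injected linear falls. Group anchor parameters: final ΔZ
  7.55/16.55/31.15/65.46 %, crossings 213.8/159.3/72.4 s. Cohort sampling
  truncates finals five noise-sd inside the band edges and crossings strictly
  between neighbouring bounds, so generated traces always satisfy their
  defining band and bound.
- **Paired cohort**: per experiment, a carpet-plus-aggregates field (carpet
  mean drawn from 0.3–4.5 µm, 2–9 aggregates of 3–9 µm apex height,
  k_true = 0.06) is rendered as a noisy stack (sd 5) and projection image;
  the "measured" impedance is the forward value at k_true with 2 %
  multiplicative Gaussian noise. At these conditions the inversion recovers
  V_IM with ~3–5 % median error and V_OT/V_IM correlate at r ≈ 0.97–0.98
  over 22 experiments.

**What the fixtures do not emulate**: optical blur/PSF and depth attenuation
(thresholding operates on intensities as recorded), intensity decay toward
aggregate tips (object intensity is flat, so the high-contrast elbow is
sharper than in real stacks), platelet adhesion kinetics in time,
hematocrit-dependent conductivity, electrode polarization and reactive
impedance components, and inter-donor variability. Passing tests therefore
validate the estimators' arithmetic, the solver, the inversion and the
decision rules under controlled truth — not the biological fidelity of any
particular acquisition.

## Problem sizes and determinism

The default solver grid has ~17 k unknowns (~0.15 s per forward solve); an
inversion takes ~14 bisection steps. The acceptance script's cohort uses 22
paired 512 × 512 experiments and completes in about a minute on one CPU.
Dense-matrix oracles and exact direct solves run on a scaled-down channel
(≤ 10³ voxels). All randomness flows through `numpy.random.default_rng`
seeds; CLI runs write a manifest (version, config hash, seed) sufficient to
reproduce outputs.

## Known limitations

- The conduction model is single-frequency and purely resistive; no
  double-layer, no phase, no frequency sweeps.
- One global scale factor maps intensity to height; spatially varying
  proportionality (per-region factors) is future work.
- The inversion's conditioning depends on surface coverage: a sparse field
  of tall aggregates over bare electrodes yields a nearly flat |Z|(k) and
  correspondingly inflated V_IM uncertainty. The package reports the
  residual and iteration count so such cases are visible.
- Raw cell constants carry a first-order edge-singularity bias; use the
  Richardson-extrapolated variant when the absolute geometry factor matters
  (ratios and round trips on a fixed grid are unaffected).
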