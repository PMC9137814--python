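# Methods

This note documents the physical models, the numerical choices and the
synthetic-data generator behind `capchip`, including the assumptions made
where the fabricated platform leaves parameters unpublished.

## Units

Capacitance is carried in femtofarad, lengths in micrometre, so
ε₀ = 8.8541878128×10⁻³ fF/µm. This keeps the model's printed anchors at
convenient magnitudes: the 10 nm Al₂O₃ passivation film computes to
8.41 fF/µm², the full 7056 µm² metal area to 59.4 pF, and the dry IDE
baseline to ~10² fF.

## Equivalent-circuit model

**Dry phase.** The IDE terminal capacitance is the sensing path plus a fixed
offset, C_equiv = C_sens + C_off:

* C_sub = α₁A + α₂P — substrate parasitic from process coefficients. The
  coefficients are proprietary to the fabrication process and default to 0,
  folding the substrate share into the calibratable offset.
* C_dir = ε₀ ε_SiO₂ P_coincide W_th / d — direct sidewall coupling between
  facing finger walls (P_coincide defaults to (n−1)·finger length).
* C_fringe = ε_SiO₂ · C_sens — the oxide-side mirror image of the air fringe,
  by symmetry of the coplanar geometry.
* C_sens — the through-air path, modelled as the per-area series stack
  passivation / air / passivation over an *effective fringe distance*
  d_eff_air: C_sens = ε₀ ε_PL ε_air A / (ε_PL d_eff_air + ε_air·2d_PL).

d_eff_air is the one calibrated constant of the lumped model: it is solved
analytically (`calibrate_d_eff_air`) so that the dry equivalent equals the
chip's experimental dry baseline of 109 fF, giving d_eff_air = 2.8686 µm with
the default geometry. The value is an explicit config field, not a hidden
constant.

**Wet phase.** Bulk electrolyte creates a solution-resistance path and a
large double-layer capacitance at each electrode; no component values are
published and none are fitted. The wet phase is represented by a saturation
flag (`WetInterface.saturated`), which the readout simulator maps to its
output rail — exactly how the hardware behaves.

**Cell-deposit phase.** With cells covering fraction conf_n of electrode n,
the per-electrode lumped interface capacitance is

C_Tn = ε₀A·[ε_PL ε_cell conf / (ε_PL d_eff_cell + ε_cell d_PL) + ε_PL(1−conf)/d_PL].

As a sum of a covered series stack and the bare passivation plate this
quantity *decreases* with coverage — the bare-plate term ε_PL/d_PL
(≈ 8.4 fF/µm²) dominates any covered term for positive cell thickness, and
chaining it in series with a fixed air term inherits the same (wrong-way)
monotonicity for every physical parameter choice. The measured equivalent,
however, *rises* with coverage: a moist cell layer is a far better dielectric
path than the air it displaces. `cell_equivalent` therefore models the
through-sample path as an area-weighted parallel mixture of vertical stacks,
per electrode:

C_path = ε₀A · mean_n[ conf_n·s_cell + (1−conf_n)·s_air ],

where s_cell and s_air are the areal capacitances of the
passivation/cell/passivation and passivation/air/passivation stacks. This
reduces exactly to the dry C_sens at conf = 0 and is strictly increasing in
each conf_n whenever s_cell > s_air (any ε_cell appreciably above 1). The
lumped C_Tn is still computed and reported in the capacitance breakdown for
reference.

ε_cell = 20 and d_eff_cell = 5 µm are assumptions — plausible for moist cell
remnants, chosen once so that confluences of a few percent produce ΔC in the
tens of fF (the scale observed on hardware); neither value is published and
both are plain config fields.

## Electrostatic field solver

The solver discretises ∇·(ε∇V) = 0 on a 2D cross-section through the fingers
with a finite-volume 5-point scheme on a tensor-product grid. Grid lines are
snapped to every material boundary — finger edges, metal top, the 10 nm film
(one cell of its own thickness), cell/water layer tops — uniform at the
requested resolution near the electrodes and geometrically graded (ratio 1.3,
capped at 16 µm) towards the far boundaries. Boundary conditions: Dirichlet
0 V on the substrate plane and the grounded comb, the drive bias on the
driven comb, zero normal field on the side and top boundaries placed 3×
the electrode span away. Capacitance comes from the field energy,
C = (2W/V²)·L with L the finger length; the energy method makes the result
independent of the drive voltage in these linear dielectrics (asserted by a
test solving at two voltages).

The resulting symmetric positive-definite system is solved by sparse direct
factorisation (SuperLU via scipy); the relative residual is verified against
the configured tolerance (10⁻⁸ default) and a violation raises a convergence
error. A direct solve was preferred over an iterative one because the thin
high-permittivity film produces a badly conditioned operator for which plain
CG stagnates; the factorisation is deterministic and meets the residual
contract by construction.

Domain details the chip does not publish are config defaults documented as
assumptions: oxide depth from the substrate plane to the finger bottoms
2.0 µm, finger (top-metal) thickness 0.9 µm, fingers embedded in SiO₂ up to
their top, the native film spanning the whole surface. The oxide depth was
chosen from an analytic coplanar-plus-plate estimate targeting the published
dry-mode magnitude before any solver run; with it the solver gives
127.0 fF at the convergence-tested resolution (0.25 µm; 0.19% change from
the 0.5 µm mesh), within the ±15% band around the published 3D-simulation
value of 117.415 fF that the unpublished domain details warrant. The 2D
per-unit-length approximation ignores finger-end effects, which is the main
systematic difference from a full 3D solve.

Validation: the solver matches the parallel-plate and two-layer-slab closed
forms to machine precision on degenerate grids (the 1% gate is far exceeded),
respects the discrete maximum principle, and is monotone in every region's
permittivity.

## Readout chain

The measured chain (capacitance-to-current converter, current-controlled
oscillator, counter) publishes its bank (200–1270 fF, 10 fF steps), its
resolution (416 aF) and its input dynamic range (400 fF) but not its gain or
intercept. The simulator therefore uses the declared linear mapping

N = clip(round(N₀ + clip(C_sense − C_ref, −IDR, +IDR)/resolution), 0, 2¹⁶−1)

with N₀ at mid-scale of a 16-bit counter so the ±400 fF IDR (±961 pulses)
sits comfortably inside the counter range. All three constants are config
fields. The sensing side is the 400 fF internal capacitor plus the IDE when
its transmission gate is on. Wet sweeps are emitted at the clip rail across
the whole bank — a flat curve that never attains the balance level, which is
all the extraction needs. Noise is additive Gaussian on pulse counts
(default sd = 1 pulse; no noise spec is published) and the GUI-style
"number of samples" averaging is reproduced by `n_average`. The two channels
share N₀ and gain and have independent noise.

## Extraction

The extraction follows the calibration-free shift procedure: linear
interpolation between the 10 fF bank points (the hardware reports ΔC to
0.1 fF, implying sub-step interpolation of some kind), crossings searched on
the first strictly descending segment bracketing the level with ties broken
toward the lowest reference value. A sweep that never attains the level is
the saturation signal and is zero-encoded. Event detection on the ΔC series:
sample introduction = first saturated sweep; evaporation onset = the first
finite sweep after a saturated block (the sharp drop from the rail), with
finite-to-finite drops larger than 10% per interval also qualifying;
steady state = first time from which the rolling standard deviation over a
30 s window stays below 1 fF. All three thresholds are config fields.

With sd = 1 pulse noise and 10-sweep averaging, the 3σ uncertainty of a shift
(difference of two interpolated crossings, including integer-rounding
quantisation) is ≈ 0.6 fF; round-trip tests recover injected offsets
(5–100 fF) and deltas (1–50 fF) within max(0.5 fF, that bound).

## Scenario generator

The generator scripts what the bench experiments do: a 1 µL droplet deposited
at t_deposit, a water layer receding linearly from 400 µm to 5 µm over
`evap_duration` (no published time law; linear is the simplest monotone
choice) and then gone, cells left behind, optional further runs without
washing (cumulative deposits), wash events that clear the surface, and bubble
artifacts (square-wave alternation between two capacitance levels — the
published observation is fluctuation without magnitudes, so the amplitude is
free). While the water layer exceeds 1 µm the trace is flagged wet
(saturated); after dry-out a moist transient (default 20 fF decaying with a
10 s constant) bridges saturation and the steady plateau, reproducing the
sharp-drop-then-settle shape of real runs.

Cell deposition is uniform random disk placement over the 350 µm × 600 µm
chamber — the real process depends on evaporation hydrodynamics and adhesion,
which are out of scope — and the confluence is the exact area fraction of
each 228 µm × 108 µm electrode covered by the disk union (shapely). The mean
coverage therefore follows the Boolean-model formula 1−(1−πr²/A_chamber)ⁿ,
which the tests verify by Monte Carlo. Default counts per 1 µL run draw from
the hemocytometer densities quoted for oral samples — about 7 neutrophils per
10 µL and about 13 epithelial cells per µL (the two printed unit conventions
are kept verbatim as separate densities, uncorrected). Radii default to 6 µm
(neutrophil) and 25 µm (epithelial); these are assumptions, the source
reports only microscope images.

All randomness flows from a single seed (placements, pulse noise), making the
scenario → footprint → extraction chain bit-reproducible.

## What the synthetic data does and does not show

Passing round-trip and phase-cycle tests demonstrate that the extraction
algorithm is correct against the declared readout model and that the
generator's physics bookkeeping (accumulation, washes, saturation coding) is
self-consistent. They do not validate the unpublished gain of the real chain,
electrochemical double-layer dynamics, evaporation hydrodynamics
(coffee-ring deposition), cell adhesion biology, or drift and 1/f noise in
real electronics — none of which are modelled.

## Problem sizes

Default test and acceptance runs use the 0.25–1.0 µm solver meshes
(10⁴–2×10⁴ nodes, sub-second solves), footprints of one-to-two hundred
108-point sweeps per channel, and a few hundred seeded placements for the
coverage Monte Carlo; these sizes make the whole suite run in well under a
minute while leaving every model at its physical defaults.
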