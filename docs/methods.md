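# Methods

`hyphasim` simulates the growth of a branching hyphal network (a
*Streptomyces*-style pellet) as a discrete–continuum hybrid: lattice-free
tips driven by a stochastic velocity process, length-triggered sub-apical
branching, a quasi-steady oxygen reaction–diffusion field on a grid, and a
four-state metabolic machine that couples the field back onto growth.
This note documents the model as implemented, the reconstruction choices
that were genuinely open, the numerical machinery, and what the synthetic
defaults do and do not represent.

## Tip elongation

Each hyphal tip `i` is a point `x_i ∈ ℝ²` with velocity `v_i ∈ ℝ²`:

    dx_i/dt = v_i
    dv_i    = β (v_avg · v_i/|v_i| − v_i) dt + α dW_i

The drift relaxes the tip's *speed* towards the average elongation rate
`v_avg` along its current heading (it exerts no torque); the noise `α dW`
perturbs both speed and direction isotropically, in the style of the
classic stochastic models of angiogenic sprout-tip migration.  Both
equations are integrated with the explicit Euler / Euler–Maruyama scheme
at `dt = t_interval / n_brownian_steps` = 4 h / 100 = 0.04 h.

**Noise convention.** The published form of this velocity equation is not
recoverable typographically, and two readings of the noise term differ
only in how the per-step increment scales with `dt`:

* `noise_scaling="dt"` (default): each component of the per-step increment
  is `N(0, (α·Δt)²)` — α acts as a per-step kick amplitude.
* `noise_scaling="sqrt_dt"`: the textbook Wiener increment `N(0, α²·Δt)`.

The two conventions give radically different tip-path geometry at the
calibrated α = β = 10.  Under `sqrt_dt` the angular diffusion is
`D_θ = α²/(2 v²) ≈ 1.3 rad²/h`: headings decorrelate within the hour, the
persistence length is ~5 μm, a single tip's 31 h displacement averages
~43 μm, and no pellet can exceed ~200 μm in diameter.  Under `dt` the
persistence length is ~120 μm, outer tips are nearly ballistic
(displacements of 150–190 μm against a 195 μm arc length), and 31 h
pellets reach the observed several-hundred-μm diameters.  Because only the
`dt` reading reproduces the documented pellet-scale morphometrics of the
calibrated model, it is the default; the conventional scaling remains
available as a config option.  Any re-calibration of α and β should state
which convention it used.

Tips paths may cross freely (the "2D+" convention: overlapping paths are
interpreted as lying in different 3-D planes), so there is no steric
collision detection; crowding enters only through oxygen consumption.

## Branching

A hypha is the polyline from its origin (germination point, then the most
recent branch point) to its tip, with length `L` accumulated from the
tip's Euler displacements.  At **every Euler step**, each actively growing
tip draws a uniform number and branches if

    Φ( (L − (l1 + l2)) / (l1sd + l2sd) )  >  U,   U ~ Uniform(0,1)

with the cumulative normal Φ parameterised by the apical length
`l1 = 28.5 μm` and the interbranch length `l2 = 7.3 μm` (sds 8.5 and
3.9 μm, summed literally, not in quadrature).  The per-step evaluation is
deliberate — the calibrated α/β values were obtained under it — and it
compounds probability with `dt`: the *realised* branch lengths concentrate
near ~23 μm rather than at the CDF mean of 35.8 μm.  The package treats
the per-step rule itself (with its `dt` cadence) as the model; tests
verify the realised branch-length distribution against an exact discrete
hazard chain built from the same CDF, not against the raw CDF.

When a branch fires:

* the branch point is placed at arc length exactly `l2` from the hypha's
  origin along its path (if `L < l2` the event is deferred — no admissible
  branch point exists yet);
* the branch angle is drawn from the equal-weight bimodal mixture
  `N(±φ, φ_sd²)`, φ = 84.0°, φ_sd = 23.0°, applied to the local path
  tangent at the branch point (the geometrically consistent reference
  direction);
* the daughter starts there with `L = 0` and speed exactly `v_avg`;
* the parent's origin moves to the branch point and its length resets to
  the **straight-line** distance between branch point and tip (a deliberate
  fidelity choice: the source describes the reset in exactly those terms,
  even though `L` otherwise accrues as arc length);
* the event *succeeds* only if the local oxygen fraction at the branch
  point is at least `maintenance_hi` (0.46), the ceiling of the
  non-growing band; otherwise it is logged as unsuccessful and nothing
  changes.

A hypha may branch repeatedly from its updated origin within one
reporting interval; nothing but the probability rule gates it.  There is
no tip splitting, fusion, or fragmentation.

## Oxygen field

Oxygen `c` (mmol/l) diffuses fast (seconds) relative to growth (hours),
so the reaction–diffusion balance is taken at its quasi-steady leading
order:

    ∇²c = d̄ c,    c = c_bulk  on the domain boundary,

where `d̄` (μm⁻²) is the consumption rate rescaled by the diffusion
coefficient.  Per grid cell (i,j):

    d̄_ij = d̄_a (A_ij + 0.70 P_ij + 0.50 M_ij + 0 · E_ij)

with `A,P,M,E` the counts of actively-growing, antibiotic-producing,
maintenance-only and dead hyphal sample points in the cell and
`d̄_a = 1×10⁻⁵ μm⁻²` the calibrated active-growth rate (adopted directly
as a parameter; the upstream dry-weight derivation is not recomputed).
Dead hyphae consume nothing.

**Occupancy counting.** Tip paths are related to the grid by dense arc-
length resampling: a sample point is dropped every
`resample_factor × grid_h` (1 μm at defaults) of growth, and each sample
increments its containing cell's count for its current state.  Cells are
half-open (`[ih, (i+1)h) × [jh, (j+1)h)`, origin at the domain centre), so
no sample is counted twice; overlapping paths stack without cap (2D+).
The resampling step is a config knob; counts — and therefore the effective
consumption strength — scale with it, which is why it is reported with any
re-parameterisation.

**Grid.** The standard pellet run uses a 400×400 μm domain with an N=200
grid, i.e. `h = 2 μm` (voxel volume 2×2×2 = 8 μm³); morphometric masks use
their own 1 μm raster (below).  The domain auto-enlarges (preserving `h`,
embedding the previous field, boundary at `c_bulk`) whenever a tip comes
within 10 μm of the boundary, as required by the high-velocity scenarios.

**Discretisation and solver.** The Laplacian uses the standard 5-point
stencil; Dirichlet boundary cells hold exactly `c_bulk`.  The resulting
sparse SPD system is solved with BiCGSTAB warm-started from the previous
field and preconditioned by a sparse LU factorisation of a recent matrix;
the factorisation is refreshed whenever the relative residual fails
`1×10⁻¹⁰`, so the solution is independent of solver path and update
cadence to that tolerance.  A hard `SolverError` reports the residual on
failure.  The solution obeys the maximum principle `0 ≤ c ≤ c_bulk`
(verified property-wise), and against the closed-form interior profile of
a uniformly consuming disk (`c(r)/c(0) = I₀(√d̄ r)`) the N=100 solution is
accurate to ~0.4%.

## Metabolic states

Each biomass sample point (and each tip) carries one of four states,
re-evaluated from the local oxygen fraction `f = c/c_bulk` (bilinear
interpolation between cell centres) at every field update:

| oxygen fraction | outcome |
|---|---|
| ≥ 0.90 | ACTIVE |
| 0.60–0.90 | ACTIVE with probability `(f−0.60)/0.30`, else PRODUCING |
| 0.50–0.60 | PRODUCING |
| 0.40–0.50 | PRODUCING with probability `(f−0.40)/0.10`, else MAINTENANCE |
| 0.15–0.40 | MAINTENANCE |
| < 0.15 | DEAD (absorbing) |

Only ACTIVE tips elongate and branch; PRODUCING and MAINTENANCE tips
freeze in place but keep their velocity and resume if re-promoted; DEAD is
absorbing and non-consuming.  Linear interpolation across the two
stochastic bands is the simplest monotone form consistent with "the
switching probability increases" — the published sensitivity analysis
found threshold details qualitatively immaterial.  The source quotes both
"production stops below 40%" and "non-growing between 15–46%"; the package
resolves the 0.40–0.46 overlap by keeping 0.40 as the production floor and
retaining 0.46 only as the branch-success gate (both configurable).
States are tracked per sub-hyphal sample point, not per whole hypha,
matching the per-cell state-resolved occupancy counting; no hysteresis or
dwell time is applied because none is described.

## Update cadence — the interval-structured loop

The integration is organised in reporting intervals of `t_interval = 4 h`,
each comprising `n_brownian_steps = 100` Euler steps.  By default the
field is re-solved and all states re-evaluated **once per interval**
(`field_update_every = 100`); growth within an interval sees the field
from the interval's start.

This cadence is a model-structure choice, not a numerical shortcut.  With
per-step (or sub-hourly) updates, the growth/state feedback self-regulates:
interior tips freeze the moment the local fraction leaves the ACTIVE band,
biomass stops accumulating, and the pellet core equilibrates just above
the all-PRODUCING floor (~0.50) no matter how strong the consumption —
no maintenance core, no sub-50% region, ever.  With per-interval updates
the network overshoots within each interval, which is what produces the
documented phenomenology: a maintenance (non-growing) core inside a
producing annulus, red-renderable sub-threshold areas of the right
magnitude, and antibiotic onset at 16 h.  The cadence is exposed as
`RunSettings.field_update_every` for experimentation.

## Run loop and randomness

Per Euler step: (1) all ACTIVE tips take a velocity + position step;
(2) lengths update and sample points are emitted; (3) each ACTIVE tip
evaluates the branching rule, locating branch points, drawing angles, and
checking local oxygen; (4) on the cadence above, rasterise → assemble
consumption → solve field → update all point and tip states.  Metrics are
recorded at every reporting interval, at requested extra times, and at
`t_end` (default 31 h; time zero is germination — two tips at the origin
with speed `v_avg` and independent uniform headings; the ~6 h spore
germination lag of real cultures is excluded from simulated time).

All randomness flows from a single integer seed through one numpy
Generator with a fixed draw order (velocity noise → branching uniforms →
branch angles → state uniforms).  Identical (parameters, seed) replays are
bit-identical; with consumption disabled the engine skips all field and
state draws, so a zero-consumption run equals the bare
elongation+branching model draw for draw.  Snapshot archives embed the
full provenance needed for replay, and `hyphasim replay` verifies it.

## Pellet morphometrics

* **Max pellet diameter** — the largest pairwise distance between hyphal
  sample points (convex-hull diameter; brute force on small or degenerate
  point sets).
* **Pellet mask, area, perimeter** — the experimental counterparts come
  from automated segmentation of fluorescence blobs, so the simulated
  network (which has zero area as a set of curves) must be
  operationalised.  The occupied raster (1 μm pixels, independent of the
  oxygen grid) is morphologically closed with a disk and hole-filled; area
  is pixel count × h², perimeter the Crofton 4-direction estimator
  (unbiased on smooth digitised blobs; the 4-neighborhood pixel-boundary
  count overestimates a digital disk by ~5%).  The closing radius is a
  mask-definition knob, not biology: it was calibrated once, jointly
  against the documented end-of-run area (60,000 μm²) and perimeter
  (1,250 μm) of the calibrated model over {5, 8, 10} μm — radius 10 μm
  reproduces both to within ~4% and is the default, always reported with
  results.
* **HGU** — total hyphal length / total tip count.
* **State-resolved areas** — each occupied oxygen-grid cell is classified
  by its dominant state (ties towards the more active state) and areas
  summed per state.
* **Live/dead rendering** — mask pixels split green/red by local oxygen
  fraction against a threshold (default 0.50), red being the simulated
  propidium-iodide analogue.  Red area is monotone in the threshold.
  `calibrate_interface_threshold` scans a threshold grid, averages red
  area over replicate runs, and returns the threshold closest to a
  measured stain area (ties to the lower threshold) together with the full
  table.

All metrics are pure functions of a snapshot: recomputing them from a
saved archive reproduces the recorded values exactly (tested to 1e-12
relative).

## Calibration utilities

* **α/β sweep** (`sweep_alpha_beta`): 4 h substrate-unlimited runs per
  (α, β, seed); min/mean/max of diameter and tip count per combination; a
  combination is flagged when both spreads lie within a supplied
  experimental mean ± sd.  The packaged comparison summary
  (`EARLY_GROWTH_REFERENCE`) is a **synthetic stand-in**: means frozen
  from a 200-seed ensemble of the calibrated model (diameter 35.2 μm,
  6.35 tips at 4 h), sds set at biological population scale (CV ≈ 45–50%,
  the scale of measured pellet-area CVs), since the reference plays the
  role of inter-pellet biological variation.  Replace it with real
  measurements for scientific use.  Sweep grids default to the stable,
  tractable region α ∈ {0.1, 1, 10}, β ∈ {0.01, …, 10}: at `dt = 0.04 h`,
  β = 100 violates the explicit-Euler stability bound (β·dt > 2) and
  α ≥ 100 drives combinatorial branching blow-up under the per-step rule.
* **Branching patterns** (`BRANCHING_PATTERNS`, `branching_pattern_report`):
  set II is the calibrated standard; set I (less frequent: l1 = 57.0,
  l2 = 11.5 μm) and set III (frequent: l1 = 16.0, l2 = 4.5 μm) are
  package-supplied representative values in the literature range for
  *Streptomyces* branching statistics, provided so the comparison runs out
  of the box.  The report asserts HGU(III) < HGU(II) < HGU(I) on means and
  shows the producing-area maximum at set II.

## What the defaults reproduce, and problem sizes

With all defaults (Table-style growth and substrate constants, 400 μm
domain, five replicate seeds, 31 h), the package computes, emergently:
mean max pellet diameter ≈ 330 μm, pellet area ≈ 62,000 μm², perimeter
≈ 1,280 μm, first antibiotic-producing points at 16.0 h, and an
interface-calibration threshold of 55% against the measured stain area of
1.71×10⁴ μm² — with a hypoxic (red) core appearing from ~28 h.  The
diameter runs some 10–15% below the documented 380 μm of the original
calibrated model; the area, perimeter, onset time and interface band
match closely.  A 31 h run takes roughly 5–20 s on one CPU; the test
suite's heaviest fixture is the shared set of five such runs, and the
calibration procedures reuse those runs rather than launching new ones.

## Known limitations

* Everything is 2-D ("2D+"): no explicit third dimension, no steric
  crowding, no 3-D oxygen geometry.
* One substrate only (oxygen); the framework's consumption interface is
  written for a single field.
* PRODUCING is a state label — there is no antibiotic concentration field
  or product kinetics.
* No fragmentation, anastomosis, or germination-lag kinetics.
* The noise convention, update cadence, occupancy counting and mask
  definition are reconstructions of an under-specified published model;
  each is surfaced as a config option and documented above, and each
  materially affects quantitative outputs.  Conclusions that depend on
  them should be checked against their alternatives.
* The synthetic early-growth reference and branching sets I/III stand in
  for unavailable experimental tables; they are labelled synthetic at the
  definition site and should be replaced with real data where available.
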