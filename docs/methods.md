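# Methods

This note documents the models behind `dcsplan`, the parameters that
matter, the numerical choices, and what the synthetic phantoms do and do
not demonstrate.

## Coordinate conventions and geometry

Patient coordinates are right-handed; the beam's-eye-view (BEV) frame is a
rigid rotation with `z_bev` pointing from source to isocenter, gantry
rotation about the patient y axis and couch rotation about z (gantry
applied after couch, IEC 61217 ordering). With this convention gantry
0/couch 0 is the identity and gantry 180° flips the `x_bev` sign, which
fixes the trimmer labelling unambiguously: TX1 sits at a more negative
`x_bev` than TX2, TY1 more negative in `y_bev` than TY2. All spot and
trimmer positions live in the isocenter plane.

Voxel phantoms are regular grids of water-relative density with 0-based,
cell-centered indexing. Structures carry fractional occupancies ζ ∈ [0,1]
computed by fixed 3×3×3 sub-voxel sampling of analytic shapes (sphere,
ellipsoid, cylinder, notched sphere). This is deterministic and testable:
a 15 mm sphere on a 2 mm grid recovers its analytic volume to well under
5%. Radiological depth is a midpoint-rule line integral of trilinearly
interpolated density from the phantom entry surface, with a range shifter
modeled purely as +38.4 mm water-equivalent thickness (4 cm polyethylene,
ρ = 0.96). Heterogeneity scatter effects are out of scope.

The variable-resolution dose grid keeps the phantom's native 2 mm voxels
inside the target/OAR region dilated by 10 mm and merges 2×2×2 blocks
into 4 mm cells elsewhere. Occupancy times volume is conserved exactly
under the merge. Wherever a formula needs a "voxel count", occupancies are
expressed in fine-voxel units (ζ · cell volume / fine-voxel volume), so
tissue totals Z_λ are invariant under the coarsening and the variable-grid
objective agrees with a fine-only grid up to dose smoothness.

## Beam model

The dose engine is analytic; only the features the planning logic consumes
are modeled with care:

* **Ranges.** Bragg–Kleeman power law, R80 = 10·α·E^p mm with α = 0.0022
  (cm/MeV^p) and p = 1.77 — clinically plausible 70–160 MeV proton ranges.
* **Depth dose.** Entrance plateau (30% of peak) with a broad Gaussian
  proximal shoulder (σ_p = 2.5 σ_d), Gaussian distal falloff of width
  σ_d = 1 mm + 0.025·R80. The distal 80%/90% crossings of the sampled
  curve sit at the layer's R80/R90 by construction.
* **Lateral fluence.** Gaussian with σ(z)² = σ_air² + (0.03·z)²; σ_air
  interpolates 6.5 → 3 mm over 70 → 160 MeV. The depth growth term is what
  makes low-energy spots broad and collimation worthwhile.
* **Trimming.** Each active trimmer edge multiplies the fluence by a
  blurred step (error function) with σ_t(z)² = (1 mm)² + (0.02·z)²,
  evaluated at the edge's isocenter-plane position. The transmission is
  exactly 0.5 on the edge, 1 beyond ~25 mm (the park distance), and
  moving any edge toward the axis can only remove dose. Nuclear halo,
  double-Gaussian fluence and edge-scatter dose are not modeled.
* **Influence matrix.** Columns are point-sampled at dose-grid cell
  centers; entries below 1e-5 of the column maximum are dropped.

**Energy layers.** The deepest layer's R80 sits at the maximum target
water-equivalent depth plus 10 mm. Successive Bragg peaks are spaced by
70% of the deeper layer's 80%–80% peak width, marching proximally until
the proximal target edge is covered. A spacing proportional to the peak
width is the only well-posed reading of a peak-overlap rule in a model
where peak depth is affine in R80; the 0.70 factor is kept as the overlap
fraction. Spots are placed per layer on a hexagonal lattice with pitch
σ_air, covering the BEV projection of the layer's target slab dilated by
10 mm; layers whose peak lies beyond the target (the distal-margin layers)
cover the nearest target band instead.

## Trimmer initialization (GA)

The implementation follows the two published formulations exactly,
including the inverse-square weights, the primary/secondary split with
ties to x, the saturation branches (boundary `|η| = μ` saturates), and the
Heaviside-gated secondary relaxation with H[0] := 1. Default parameters:
Δz = 1 mm, Δr = 5 mm, f_min = 1 mm, μ_p = 1 mm, μ_s = 5 mm; a′ = 1 mm,
μ′_max = 2 mm, f′_max = 25 mm, f′_min = 1 mm, c_s = 5.657 mm⁻¹, k_s = 15.
(`a′` is carried in the parameter set but enters no formula.)

Decisions where the formulation is silent:

* Voxels exactly on the spot axis are excluded from the marginal sets
  (their inverse-square weight is unbounded); the nearest-voxel distance
  r* likewise excludes them.
* A spot is *inside* the target when the target occupancy of the laterally
  nearest slab cell at its axis exceeds 0.5.
* An outside spot with an empty marginal slab (no target voxels within the
  Δz window around its R90 — typical for the distal-margin layers) is
  classified uncollimated and parked.
* When a vector component is exactly zero the negative-side trimmer
  (TX1/TY1) is taken as active.
* Free-agent (opposing) trimmers park at f′_max; they are sequencing
  currency only and are never re-optimized dosimetrically.

Note that on the unsaturated branch the outside offset μ − |η| can fall
below f_min (e.g. μ_s = 5, |η_s| = 4.99); the formulas are implemented as
printed rather than clamped.

## Weight and position optimization

The weight objective O² penalizes occupancy-weighted squared over/underdose
per tissue, normalized by the tissue's voxel count. The solver is a
projected-gradient scheme: a Lipschitz step from power iteration on the
weighted normal matrix, projection to w ≥ 0, and step-halving whenever an
iterate would increase O² — so the objective trace is non-increasing by
construction. It terminates on relative change < 1e-7 or an iteration cap
(400 by default). On equality objectives it matches a non-negative
least-squares reference solve to within 1% in objective value.

MGD moves one spot at a time: the per-spot objective F_j sums each
tissue's integral unit-weight dose over its member voxels, scaled by
β_λ/Z_λ, with β lower for targets (0.1) than healthy tissue (ring 1, OARs
10) so descent pushes spots out of healthy tissue. The gradient is a
central difference with 1 mm spacing on a 5×5 candidate grid of ±2 mm and
the update moves exactly |r*|γ (γ = 0.3 by default) along the negative
normalized gradient, where |r*| is the BEV distance to the nearest target
voxel at the spot's R90 depth. The pipeline runs GA → weights → MGD →
weights; spots whose step |r*|γ would be under 0.2 mm are skipped (interior
spots have r* ≈ 0), moves are accepted unconditionally with at most a few
outer iterations per spot (2 in the demo configuration, 10 by default),
and a moved spot's trimmers are re-initialized by re-running GA because
offsets are defined relative to the spot axis. The candidate-grid
extent/resolution, γ and the alternation schedule are design choices; none
are pinned by the published formulation.

Post-processing removes spots below the 0.015 MU delivery threshold and
rescales the remaining weights by one global factor so target D95 equals
the prescription; plans are checked against D95 ≥ prescription and target
D_max ≤ 107%.

## Delivery-time model and sequencing

Transition time between consecutive groups is the maximum of the
energy-switch time (1.5 s decrease / 7 s increase, 0 within a layer) and
the four trimmer settle times — trimmer motion and energy changes run
concurrently, everything else sequentially. Beam time is 6.6 ms/MU.
The trimmer settle model is the sigmoid
τ(x) = −(1/g₁)·ln(x/(x−0.05 mm) − 1) + g₂ with logarithmic
jerk/distance dependencies g₁ = a₁ + b₁ln ξ − c₁ln(x+1),
g₂ = a₂ + b₂ln(x+1) − c₂ln ξ. The published characterization does not
include coefficient values, so the defaults are calibrated such that
typical 5–50 mm moves cost ~0.2–0.4 s at the 300,000 mm/s³ jerk —
consistent with tens of seconds of collimation overhead across a few
hundred groups — and are fully config-overridable. Moves within the
0.05 mm settle tolerance (the log's domain boundary) cost zero. A 90 ms
operational recalibration delay can be added per transition; the default
time model excludes it.

ACO runs over the desirability matrix Ω = 1 − τ/τ_max built from *pure*
trimmer times, while total time uses the energy-capped max rule — the two
definitions differ and both are kept as specified. Layers are delivered as
contiguous blocks in strictly decreasing energy (so inter-layer switches
cost 1.5 s in normal operation). The first ant of each iteration is a
nearest-neighbour chain from that iteration's start group (deterministic
lowest-id start first, then randomly selected starts); subsequent ants
sample by pheromone^1 · Ω². With one ant and one iteration the search
reduces exactly to the nearest-neighbour heuristic, and for ≤ 6 groups in
a layer it recovers the exhaustive optimum. Defaults: 20 ants, 50
iterations, evaporation 0.1 (8 ants × 6 iterations inside the regrouping
loop of the demo pipeline).

Regrouping starts from one group per collimated spot plus one parked
uncollimated group per layer, raises the permitted group size by one per
iteration, and greedily merges same-layer pairs with minimal trimmer
movement (max over the four edges, ties by summed movement, then lowest
group ids). A merged group's trimmer set is the per-trimmer
least-collimating envelope of its members' edges, so no member is ever
collimated tighter than GA prescribed. The loop keeps the best sequence
seen, so its time trace is non-increasing; it stops at the 70 s goal or
returns best-effort with a warning when fully merged.

## Plan metrics

DVH statistics are ζ-weighted by default (binary-mask option available;
which convention clinical systems use varies). D_2cc interpolates the dose
at the exact 2 cm³ boundary of the hottest volume and falls back to D_max
(flagged) for structures under 2 cm³. Paddick CI uses the ζ-weighted
target volume against a plan-level prescription-isodose volume counted
over whole cells at their centers (no isodose-surface interpolation; at
2 mm resolution on the demo phantoms the sub-voxel correction is smaller
than the metric differences being compared, and both plans in a comparison
use the identical convention). DGI is the V(≥0.5 Rx)/V(≥Rx) ratio on the
same convention. The 10 mm normal-tissue ring is a Euclidean dilation of
the target surface excluding the target.

Gamma analysis (3%/3 mm, 10% threshold by default) normalizes globally to
the reference maximum, excludes sub-threshold points, and searches
exhaustively over a trilinearly interpolated sub-voxel lattice (3 points
per voxel per axis) within twice the distance criterion, with
shortest-distance-first early termination. It is validated against a naive
per-point exhaustive search on the same lattice.

## Synthetic phantoms and what the tests show

The generator produces water boxes with analytic targets/OARs — uniform
density, no CT calibration, no setup uncertainty, no anatomical
heterogeneity. Demo plans use a per-fraction 2 Gy prescription so monitor
units, the 0.015 MU threshold and the 6.6 ms/MU beam time interact on a
clinically meaningful scale. Problem sizes are desk-scale by choice: 80 mm
boxes at 2 mm grid, one to three beams, a few hundred spots over ~5
layers.

Passing tests therefore demonstrate the *mechanics* and *directions* of
dynamic collimation planning — trimmed beamlets never add dose, collimated
plans spare the peritumoral ring and sharpen the gradient index at equal
target coverage, sequencing meets a 70 s goal on a ~300-spot field — not
clinical effect sizes. Patient-level magnitudes depend on real anatomy,
a Monte Carlo-grade dose engine and measured machine kinematics, all of
which are outside this package's scope.

## Numerical notes

* All randomness (ACO, density noise) flows through seeded
  `numpy.random.Generator` instances; fixed seeds give bit-identical runs.
* Ray-box entry handles beams parallel to grid axes explicitly; rays that
  miss the phantom contribute only the range-shifter term.
* Degenerate guards: empty structures, all-zero influence columns,
  crossing trimmer edges, all-sub-threshold weights and empty prescription
  isodose volumes raise informative errors rather than propagating NaNs.
* Tie-breaks are deterministic everywhere (lowest id / x-axis primary on
  exact ties; Heaviside H[0] := 1).
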