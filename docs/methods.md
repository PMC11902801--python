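# Methods

## Model

The system is simulated with dissipative particle dynamics in reduced
units (`r_c = m = k_BT = 1`). Each bead represents a fixed volume of
matter (111.03 Å³, 54 amu), so that at number density ρ = 3 one cut-off
cell `r_c³` holds three beads and the cut-off maps to 6.93 Å. Three
forces act between non-bonded beads inside the cut-off:

- conservative soft repulsion `a_ij (1 − r) ê`,
- dissipative drag `−γ (1−r)² (ê·v_ij) ê`,
- random kicks `σ (1−r) θ_ij Δt^(−1/2) ê`,

with `σ² = 2γk_BT` enforced at construction so the pair thermostat
satisfies fluctuation–dissipation. All pair forces are antisymmetric;
total momentum is conserved to accumulation error (≲1e-13 per step in
practice).

Like-bead repulsion comes from matching water compressibility,
`a_ii = 75 k_BT/ρ = 25`. Unlike-bead repulsions are linear in the
Flory–Huggins parameter, `a_ij = a_ii + 3.27 χ_ij`; the packaged table
(`data/interactions.csv`, reduced units) supplies the 8×8 canonical
values and the inverse map `χ = (a_ij − a_ii)/3.27` is exposed for
consistency checks. χ values themselves are inputs here: computing them
from atomistic mixing energies is out of scope. Three species names are
aliases for chemically identical groups on different polymers
(N3→N2, O3→O2, O4→O2); aliases are resolved at lookup time so the
canonical table stays the single source of truth.

### Unit-system consistency

The internal consistency check is `r_c³ ≈ ρ·V_bead` (332.81 vs 333.09 ų,
0.08 %): one density-grid cell of volume `r_c³` holds ρ beads.

## Topology

Wall polymers are bead-spring chains of 20 repeat units. The
composition of each repeat is fixed (Cts: N1,N1,O4; Alg: N3,N3,S,O3;
MC: N2,N2,O1,O2; citral: C1–C2; water: W), but the intra-repeat bond
wiring is not uniquely determined by composition. The packaged default
follows the chemical picture of a ring backbone with substituents: the
two N beads form the backbone, side groups hang pendant from it, and
consecutive repeats join N-to-N. Every expanded molecule is validated
to be a tree (n beads, n−1 bonds, connected). Templates are plain YAML
and can be overridden wholesale; no angle or dihedral terms exist in
the model.

Bonds are harmonic with zero rest length and `k = 4` (reduced). The
force constants not fixed by the model itself follow the standard DPD
protocol: `γ = 4.5`, hence `σ = 3`, velocity-Verlet predictor weight
`λ = 0.65`, `Δt = 0.05` reduced time. The time step is read as reduced
time; a mapping to physical nanoseconds is not defined for this
parameter set.

## System building

A composition recipe lists volume fractions (percent) of
H₂O/Cts/Alg/MC/citral; all forty studied formulations ship as named
presets that sum to 100 ± 0.15 (values are rounded to 2 decimals).
Since all beads share one volume, volume fraction equals bead-number
fraction. Counts are integerized by flooring each non-water component
at whole molecules and letting water absorb the remainder, so the bead
total is exactly `round(ρL³)` and solvent-dominated systems stay exact.
A nonzero component whose budget rounds to zero molecules warns — the
desk-scale box is below that component's granularity.

Initial configurations are fully random: polymers are placed as random
walks with bond length 0.86 r_c (the balance point of the k = 4 spring
against the a = 25 soft repulsion), wrapped periodically; velocities
are Maxwellian at k_BT = 1 and shifted to exactly zero total momentum.
Building is bit-deterministic in the seed.

## Integration

One step of the modified velocity-Verlet scheme: positions advance by
`vΔt + ½Δt²f`, the dissipative force is evaluated at the predicted
velocity `v + λΔt f`, and velocities are corrected with the mean of old
and new forces. Neighbor search sorts beads into a cell grid
(edge ≥ r_c) each step; boxes too small for three cells per side fall
back to all-pairs with a warning. The per-pair random variate is a
counter-based hash of (step, ordered pair indices, seed) mapped to a
uniform on [−√3, √3] — zero mean, unit variance, symmetric in the pair —
which makes trajectories independent of pair iteration order and
bit-reproducible. Exact bead coincidence (probability zero, possible
only in pathological inputs) is handled by a capped push along a hashed
direction. A displacement exceeding half the box in one step aborts
with an instability error advising a smaller `Δt`; NaN positions abort
likewise.

Production schedule: 250,000 steps with a frame every 5,000 steps
(51 frames including the start) in a 28.86 r_c (200 Å, ~72,000-bead)
box. Desk-scale manifests keep the recipe but shrink the box (default
12 r_c, 5,184 beads) and the run (default 30,000 steps); they are
explicitly flagged as non-production-scale.

## Observables

- **RDF**: species-pair g(r), shell-volume and density normalized so an
  ideal gas gives 1; minimum-image distances; default averaging window
  is the last half of frames, and the production window (last 50,000
  steps sampled every 100 → 500 frames) is exposed as a helper.
  Reported against Å via r_c = 6.93 Å when needed.
- **Radial concentration profile**: per-species bead density in
  spherical shells (default bin 1 Å = 0.144 r_c) around the aggregate
  center. The center of mass of the non-water beads is computed by the
  circular-mean method (each axis embedded on a circle) so aggregates
  straddling the periodic boundary are handled exactly. Bin edges cover
  the maximal minimum-image distance, so per-species counts sum exactly
  to bead totals.
- **MSD / diffusion**: origin-frame MSD over unwrapped coordinates
  (the engine integrates unwrapped positions alongside wrapped ones);
  `D = slope/6` from a least-squares fit over the last half of the lags
  by default. Wrapped-only trajectories are rejected with an
  instructive error. The single-origin curve is statistically noisy as
  a D estimator (its relative error at 1,000 beads × 2,000 frames has a
  ~8 % 90th percentile on a synthetic Brownian walk), so a separate
  multi-time-origin estimator `diffusion_coefficient()` averages
  displacement statistics over ~20 origins before taking the slope;
  its error stays within ~5 % under the same conditions and it is the
  estimator to use when the number rather than the curve is wanted.
- **Clusters**: connected components of the within-cutoff contact graph
  (periodic k-d tree + sparse connected components); default cutoff
  1 r_c.
- **Shell order**: per-species mean radial distance from the aggregate
  center — the quantitative form of "which layer is outermost". A
  single snapshot of a desk-scale aggregate fluctuates enough that
  adjacent layers (citral core vs. the N1 backbone) can swap rank
  frame to frame, so the ranking is taken from the per-frame order
  averaged over the last ten frames (`shell_order_trajectory`), the
  same late-window averaging applied to production RDFs.
- **Contact fraction**: A–B contacts over all contacts among two
  groups; ~0.5 when mixed, → 0 under demixing.

## What the scaled-down runs show — and what they do not

The desk-scale boxes (12 r_c, 5,184 beads, 20,000–40,000 steps) contain
only a couple of wall-polymer chains and ~14 citral molecules, so they
probe the *mechanism* — hydrophobic collapse, wall wetting of the core,
hydrophilic groups turning outward — not the production-scale capsule
morphology (layer thicknesses, defect structures, multi-capsule
competition). Layer-ordering checks are therefore stochastic
(majority over three seeds): at this size a single seed can freeze a
citral blob against, rather than inside, the polymer. Quantities such
as RDF peak positions at production scale are not asserted. The
synthetic systems also idealize real formulations: strictly neutral
(no electrostatics, no pH), monodisperse chains of degree 20, and a
parameter table taken as given.

## Problem sizes and tolerances

- Thermostat audit: 3,000-bead solvent box, 10,000 steps; kinetic
  temperature within 3 % of 1 (the small systematic drift of the
  Groot–Warren scheme at Δt = 0.05 is inside this band).
- Momentum audit: |ΣP| < 1e-8 after 1,000 steps of a 500-bead box.
- Demixing: 1,536-bead 50/50 box, 20,000 steps; A–B contact fraction
  < 0.25 at `a_AB = 80` vs ≈ 0.5 at `a_AB = 25`.
- Estimator recoveries: ideal-gas RDF mean within 5 % of 1; Brownian
  walk D within 10 % (1,000 beads × 2,000 frames).
- Structure: chitosan–citral boxes run 40,000 steps (aggregation of the
  sparse polymer needs longer than the alginate systems' 20,000); the
  citral-in-water collapse check runs 60,000 steps, since coalescence of
  the last two citral droplets is diffusion-limited with a slow tail.

## Design choices

- Interaction table and recipes ship as delimited text; templates as
  YAML — swappable without code changes.
- Alias resolution at lookup, not matrix expansion.
- Water absorbs integerization remainders (exact totals).
- Counter-based noise (reproducibility independent of enumeration
  order) instead of a sequential RNG stream.
- Desk-scale default L = 12 r_c; production scale behind an explicit
  flag/manifest.

## Known limitations

- No electrostatics: charge-mediated wall–wall effects are outside the
  model; core–shell ordering here is driven purely by the repulsion
  table.
- The intra-repeat bond graph is a documented modeling choice, not a
  measured structure.
- Single-CPU engine; production-scale runs (~72k beads × 250k steps) are
  supported but take hours, not minutes.
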