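# Methods

This note documents the models, conventions and numerical choices behind
glycopucker, in the spirit of a methods appendix: what each component
computes, which knobs matter, what the synthetic data do and do not
emulate, and the design decisions taken where more than one convention
exists in the literature.

## Cremer–Pople coordinates and the ideal-ring inverse

Ring atoms are taken in the order j = 1..6 = O5, C1, C2, C3, C4, C5.
The six positions are centered on their geometric mean; the mean plane
is defined by R′ = Σ R_j sin(2π(j−1)/6) and R″ = Σ R_j cos(2π(j−1)/6)
with unit normal n = R′×R″/|R′×R″|; out-of-plane displacements are
z_j = R_j·n, from which q₂, φ₂, q₃, Q, θ, φ follow.  With this ordering
and a ring traversed clockwise when viewed from the normal's side, the
⁴C₁ chair maps to θ = 0 — the convention used throughout carbohydrate
enzymology, so Mercator plots have ⁴C₁ at the top.

`build_ideal_ring` is the exact inverse: a planar regular hexagon
(circumradius = side = bond length, default 1.52 Å, a typical pyranose
C–C distance) displaced along its normal by the closed-form pattern
z_j(Q, θ, φ).  Because the displacement pattern contains only Fourier
modes of frequency 2 and 3 around the ring while the mean-plane sums
probe frequency 1, the construction roundtrips through
`compute_cremer_pople` to machine precision; the test suite asserts
1e−6 on 1000 random draws and observes ~1e−12.

Angular coordinates are reported as undefined (NaN) below Q = 0.1 Å:
near the center of the puckering sphere θ and φ are numerically
meaningless, and classification refuses such rings rather than
guessing.  Units are Å and degrees at every module boundary; radians
never cross one.

## The conformer catalog

The 38 canonical conformers are not copied from a literature (θ, φ)
table.  Each is constructed from its geometric definition on the
hexagon template — chairs as the alternating pattern, boats as a para
pair displaced to the same side, twist-boats as a meta pair displaced
to opposite sides, envelopes as a single displaced atom, half-chairs as
an adjacent antisymmetric pair — and run through `compute_cremer_pople`;
the resulting table is frozen as package data and a test asserts the
regeneration matches.  This makes label placement self-consistent with
the package's φ origin regardless of which of the several published
φ-offset conventions a reader is used to.  Consequences worth knowing:

- boats and twist-boats land exactly on the equator at φ multiples of
  30° (¹S₃ at 210°, ¹,⁴B at 240°, ⁴E at 240° on the northern tropic, so
  the boat→envelope→chair route of the catalytic itinerary is a
  straight march north in these coordinates);
- envelopes land exactly at θ = atan(√2) ≈ 54.74°;
- half-chairs land at θ ≈ 50.77°, about 4° off the idealized lattice
  tropic — the geometric four-atom-coplanar half-chair is a slightly
  different point than the equal-mixture lattice position.  Since
  classification is nearest-reference against this same catalog, the
  offset is internally consistent.

Classification uses the spherical geodesic distance and emits a
composite "A/B" label when the two nearest references differ by less
than `tie_tol` (default 10°) — conformations midway between a boat and
the adjacent twist-boat are genuinely blended, and the composite is the
honest label.  Composite components are ordered lexicographically
("1,4B/1S3").

## Reaction collective variables

The two CVs are explicit distance combinations over a user-supplied
role map (anomeric carbon, glycosidic oxygen, acetamido carbonyl
oxygen, the acid/base aspartate's proton and carboxylate oxygen, water
oxygen and proton).  Roles are never inferred from geometry: which
carboxylate oxygen holds the proton is mechanism-critical and must be
an explicit, auditable choice.  The sign convention makes reactant-like
frames negative and product-like frames positive.  Per-frame series
keep gap markers (None) for unevaluable frames instead of dropping
them, so CV series stay aligned with other per-frame observables.

## Metadynamics engine

Dynamics run in CV space only, on analytic model potentials.  This is a
deliberate scope boundary: the engine exists to validate the
reconstruction and landscape analysis against known ground truth, not
to emulate atomistic forces.  The integrator is overdamped
Euler–Maruyama Langevin: Δs = −μ∇(U+V_bias)Δt + √(2kTμΔt)ξ with
μ = 1/friction; defaults kT = 0.596 kcal/mol (≈300 K), friction 1,
Δt = 1e−3.  The timestep satisfies μ k Δt ≪ 1 for every fixture
potential's stiffest curvature (harmonic validation runs at k = 10
give μkΔt = 0.01); non-finite forces abort with a diagnostic.

Hills are isotropic-per-dimension Gaussians deposited every `pace`
steps; well-tempered deposition scales the height by
exp(−V_bias/((γ−1)kT)).  The accumulated bias is kept on a grid (601
points in 1D, 161² in 2D) so the per-step bias force is O(1) in the
number of hills; depositing adds the Gaussian to the grid once,
vectorized.  Identical parameters and seed give bit-identical hill
logs.  Periodic CV dimensions use minimum-image distances; non-periodic
dimensions reflect at the domain walls.

Reconstruction negates the bias sum (scaled by γ/(γ−1) when tempered)
and shifts the minimum to zero.  Because the instantaneous bias
oscillates around the converged profile by roughly one hill height, the
reconstruction can average the (min-shifted) estimate over deposition
checkpoints spanning the tail of the run (`average_tail=0.5` averages
over the last half).  The recovery pipeline uses this; it reduces the
barrier error from ~10% to ~2–3% at the run lengths used.

Recovery runs use 1.2M steps, pace 250 (4800 hills), height
0.12 kcal/mol, σ = 0.07 CV units, and a bias factor sized to the
designed energy range, γ = 1 + (range + 8 kcal/mol)/kT.  These sizes
were chosen so a single-CPU run of all three designed profiles
completes in about a minute while recovering barriers and reaction free
energies within a few percent; they are the package's study conditions,
not tuned per seed.

## Landscape analysis

Surfaces live on regular grids (default 1° × 1° for (φ, θ); finer grids
add nothing at the precision of the reported quantities).  Topology:
φ wraps; the θ = 0 and θ = 180 rows are each collapsed to a single
logical point, because the chairs are points on the puckering sphere,
not circles.  Connectivity is 8-neighbor to avoid staircase artifacts
in minimax paths.

Minima are found by topographic persistence: cells are flooded in
energy order with union-find merging, and a basin survives only if the
saddle at which it merges into a deeper basin lies more than
`depth_tol` (default 0.5 kcal/mol, half the customary 1 kcal/mol
isoline unit) above its own minimum.  Barriers are minimax: Dijkstra
with max-energy path cost, ties broken toward lower accumulated energy
so recovered paths hug the valley floor; the saddle is the arg-max on
the optimal path, and barrier(a→b) − barrier(b→a) = E(a) − E(b) holds
by the shared saddle.  Minimum-energy paths relax the Dijkstra path by
discrete steepest descent from the saddle toward each minimum, falling
back to the Dijkstra segment when descent drains to a different basin.

Itinerary assignment classifies every path point against the catalog
and reports stations: the endpoints, the saddle (bracketed "[X]‡"), and
any interior point that actually visits a reference conformer (nearest
distance below `station_radius`, default 10°).  Transitional cells
between stations — inevitably closest to some conformer, but 15–25°
from all of them — are not stations; without this filter every path
would string together half-a-dozen incidental labels and the canonical
three-station grammar ("1,4B/1S3 → [4E]‡ → 4C1") would be unreachable.
Consecutive duplicates collapse; a single-basin path yields one label,
no transition-state marker, and a warning.

## Synthetic data: what it does and does not emulate

Generators are all seed-deterministic and return ground truth alongside
the data; recovery tests consume only the generated input and compare
against the recorded truth.

- Ring trajectories interpolate waypoints along great circles of the
  puckering sphere with linear Q, convert to Cartesian via
  `build_ideal_ring`, and add i.i.d. Gaussian noise (0.02 Å in the
  study-condition tests, a thermal-vibration scale).  They emulate the
  conformational route, not bond-length/angle dynamics, exocyclic
  substituents, or correlated thermal motion.
- Designed landscapes are built as a valley along the geodesic
  polyline basin–saddle–basin: a cosine on-path energy profile through
  the designed stationary energies plus a smooth transverse rise toward
  a 12 kcal/mol plateau.  Minima and saddle energies are then exact by
  construction (grid discretization aside), which is what makes the
  barrier and itinerary tests sharp.  Real conformational landscapes
  are rougher and multi-channel.
- Reaction profiles are piecewise-cosine double wells realizing the
  requested barrier and reaction free energy exactly (C¹, zero slope at
  the stationary points, harmonic confinement outside); the designed
  values 16.1/−10, 11.1/−6.8 and 5.0/0 kcal/mol span the deep-well and
  shallow-well regimes of interest.
- Water trajectories place a water oxygen uniformly inside the 2 Å
  probe sphere with per-frame probability p (strictly outside
  otherwise), so the estimator's binomial error is the only source of
  recovery discrepancy.  No water structure, exchange kinetics or
  hydrogen bonding is represented.
- Toy active-site frames realize the transition-state distances by
  collinear chain placement, exact to machine precision — worked
  examples for the CV arithmetic, nothing more.

Passing these tests therefore demonstrates the correctness of the
coordinate transforms, samplers, estimators and landscape algorithms —
not that the package reproduces any particular enzyme's energetics,
which requires the electronic-structure layer that is out of scope
here.

## Probe-sphere occupancy

The probe center is recomputed per frame as the midpoint between the
anomeric carbon and the carboxylate-group centroid (mean of the two
carboxylate oxygens and the carboxyl carbon — the group, not a single
atom; the atom set is configurable).  Inclusion is a closed ball
(≤ radius) for deterministic boundary behavior.  The primary statistic
is the single-sphere definition; a dual-distance mode (water within the
radius of both anchors) is provided because the two phrasings of the
criterion differ and the choice should be explicit.  Waters are
identified by residue name (HOH/WAT/TIP3/SOL dialects) and their oxygen.

## Known limitations

- Six-membered rings only; no furanose pseudorotation.
- Half-chair catalog positions sit ~4° off the idealized lattice tropic
  (see above); classifications near the tropics inherit that offset.
- The metadynamics engine has no multiple walkers, adaptive hills, or
  reweighting; 2D runs are supported but the recovery pipeline
  validates 1D profiles.
- The 1° grid quantizes saddle locations and energies; reported
  barriers carry a discretization error of order the local gradient
  times the cell size (≈0.05 kcal/mol on the designed fixtures).
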