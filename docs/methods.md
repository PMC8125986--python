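# Methods

## Model

`erodesim` simulates enzymatic surface erosion of a solid polymer part as
stochastic removal of tetrahedral mesh elements, guided by experimental
mass-loss data. The model's assumptions:

* **Surface erosion only.** Enzymes do not penetrate the bulk, so only
  boundary elements — those with at least one triangular face not shared
  with another active element — can be removed. Interior (bulk) hydrolysis,
  autocatalysis, water diffusion, molecular-weight and crystallinity
  evolution are all outside the model; the experimental schedule implicitly
  carries their net effect on the mass-loss rate.
* **Constant density.** % mass loss ≡ % volume loss. When per-time
  densities are known, `material.mass_to_volume_loss` converts a mass
  schedule to the volume schedule the engine actually consumes
  (`vol% = 100·(1 − (1 − mass%/100)·ρ₀/ρ_t)`).
* **Guidance, not kinetics.** The engine does not model rate constants; it
  *interpolates geometry* between measured mass-loss references. Time
  enters only as the label of each reference snapshot.

One iteration works on a frozen entry snapshot: exposure counts, the
boundary volume `boundvol`, the boundary-mean exposed-face count
`nfacesavg`, and the amplification factor `X` are computed once, then all
per-element decisions are taken against them (removals do not update
exposures mid-iteration). With `deficit = ab_vol_loss(m) − ab_removed_volume`:

* `boundvol > deficit` → **Monte Carlo**: `X = deficit/(nfacesavg/4·boundvol)`,
  `P_e = X·n_e/4`, independent Bernoulli removals.
* otherwise → **boundary elements**: the whole boundary layer is removed.
  This crossing move matters when consecutive references are far apart
  (for the composite schedule the 1.12 % → 13.68 % gap takes three peels
  at cluster-scale resolution, one at desk scale).

Convergence per reference is `removed% > reference% − tolerance` with a
strict inequality and an absolute tolerance in percentage points
(default 0.01). One large step may cross several references; the loop then
saves one snapshot per reference before advancing.

## Removal rules

Two rules decide an element's fate from its probability `P_e`; both are
exposed, and the difference between them is the one genuinely open design
point in the procedure:

* **expected-volume** (default): remove iff `U < min(P_e, 1)`, `U ~ U[0,1)`.
  Then `E[removed volume] = Σ min(P_e,1)·v_e ≈ deficit`, which is the
  design intent of the amplification factor: a Monte Carlo iteration
  removes, in expectation, exactly what is missing. The published
  per-iteration tables (e.g. a first iteration removing 1.21 mm³ of a
  4.62 mm³ boundary at `X ≈ 1`, i.e. ~26 %) are consistent with this rule.
* **threshold-transform**: remove iff `z = −λ·ln(1−R) < P_e`, `R ~ U[0,1)`,
  λ = 0.00812 by default. The effective removal probability is
  `1 − exp(−P_e/λ)`, which saturates to ~1 for any `P_e ≳ 0.05` at that λ —
  an essentially complete boundary peel whenever X is not tiny, which the
  printed iteration tables contradict. The rule is kept as a literal
  implementation of the published transform, with λ configurable.

`P_e` is clamped at 1 before use as a Bernoulli probability (clamping can
bias a step's expectation low; the next iteration's freshly computed X
absorbs the shortfall). Per-element draws are consumed in ascending
element-id order from a single seeded NumPy `default_rng` stream, so runs
are bit-reproducible for a given (mesh, schedule, config, seed).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `removal_rule` | `expected-volume` | — | see above |
| `lam` (λ) | 0.00812 | — | exponential threshold rate (threshold rule only); larger λ slows erosion |
| `tolerance` | 0.01 | percentage points | absolute convergence band below each reference |
| `max_iterations` | 10000 | — | stall guard; converts an empty-boundary/never-converging loop into an error carrying the partial records |
| `probability_clamp` | on | — | cap P at 1 |
| `radial_divisions`, `axial_divisions` | 8, 40 | — | cylinder generator resolution (61 440 elements at defaults) |

## Mesh generation and geometry

The built-in generator produces a structured all-tetrahedral cylinder: a
`(2·nr)²` square grid is mapped concentrically onto the cross-section disk
(square rings → circles, avoiding the sliver cells of a polar fan), each
quad is split along whichever diagonal balances its two triangle areas,
and each triangle is extruded layer by layer into prisms cut into 3
tetrahedra by the sorted-vertex rule (diagonals keyed to global node
order), which guarantees a conforming, watertight mesh. Properties, all
test-asserted: no face has more than 2 owners; total volume is exactly the
inscribed `8·nr`-gon area × length (0.18 % below the analytic cylinder at
nr = 8, 0.05 % at nr = 16); element volumes are near-uniform (max/min < 2);
doubling axial divisions doubles the element count at identical volume.

Default problem size is 61 440 elements (nr = 8, na = 40) for the
1.9 mm × 50.3 mm filament — the package's desk-scale working resolution;
the guidance mechanism pins removed-volume outputs to the schedule, so
they are resolution-independent up to one stochastic step's overshoot.
One consequence of resolution worth knowing: the boundary layer of the
61 k-element mesh holds ~9.8 % of the part volume, so gaps between
references smaller than that are crossed by Monte Carlo iterations alone;
the full-boundary peel engages on larger gaps (the composite schedule's
12.6-point gap) or on finer meshes, where the boundary layer is thinner.

MSH I/O reads ASCII v2.2 and v4.1 (element type 4 only; surface elements
are counted and ignored), and writes ASCII v2.2 plus legacy VTK
unstructured grids. Writing renumbers nodes and elements contiguously in
ascending original order, making the serialization canonical:
write → load → write is byte-identical. Degenerate tetrahedra
(volume < 1e-12 mm³) are rejected at construction with the offending
element id, since they would silently corrupt the volume accounting.

## Normalized-factor transfer

A guided run is summarised by its per-iteration factors
`f_i = (removed volume in iteration i)/(boundary volume at entry)` ∈ [0, 1]
(1 for a boundary peel). Replaying on a new mesh, the amplification factor
is chosen as `X = 4·f·boundvol / Σ n_e·v_e` — the volume-weighted form —
so that `E[removed boundary-volume fraction] = f` *exactly*; the unweighted
`X = 4f/nfacesavg` matches only when exposure and element volume are
uncorrelated, which a boundary mixing corner, rim and side elements
violates. Self-consistency (factors extracted from a geometry and replayed
on it reproduce the original trajectory on average) is test-asserted over
30 seeds.

## Synthetic data and what the tests show

All test inputs are generated in-process: hand-written 1- and 2-tet MSH
fixtures, generated cylinders from 288 to 61 440 elements, and the
built-in experimental schedules (PCL: 0.84 % @ 4 h, 6.16 % @ 24 h — the
saturated 5.88 % @ 48 h point is excluded since a pure-erosion model
cannot regain mass; composite: 1.12/13.68/16.15 % @ 4/24/48 h). The
generated cylinder emulates the *geometry* of the real filament but not
surface roughness, preferential erosion at filler-rich sites, or void
formation observed microscopically; passing tests therefore validate the
volume bookkeeping and the guidance mechanics, not the spatial realism of
the predicted erosion front, which inherits the isotropy of the
probability model.

Statistical tests (step-expectation calibration, transfer
self-consistency) use 30–50 fixed seeds and 3-standard-error bands, on a
~6 000-element cylinder to keep the suite fast; exposure-count correctness
is asserted against an independent O(E²) all-pairs face-matching oracle on
meshes ≤ 500 elements, and quadratic modulus fits against an explicit
normal-equations solve.

## Numerical choices and edge cases

* Absolute-volume accounting is incremental (`ab_removed_volume` summed per
  step) and is test-checked against the active-set volume sum at 1e-9
  relative over full runs.
* Strict inequalities follow the selection and convergence definitions:
  deficit exactly equal to the boundary volume → boundary peel; removed %
  exactly at reference − tolerance → not converged.
* An empty boundary with an unmet reference raises a stalled-simulation
  error; `max_iterations` bounds pathological no-removal loops.
* Modulus fitting requires ≥ 3 distinct abscissae (rank of the quadratic
  Vandermonde); model intercepts must be positive.
* The fitted-vs-preset coefficient comparison for the experimental mean
  points is reported by the fitting API but deliberately not asserted:
  which points (means vs replicates, with or without the saturated 48 h
  datum) produced the published coefficients is not recorded, so the test
  suite only pins the fit to the independent least-squares oracle.

## Known limitations

* Single-material, isotropic erosion probability; no spatial heterogeneity
  (filler distribution, crystallinity gradients).
* Geometry prediction between references is not time-resolved: snapshots
  exist only at schedule times.
* The mesh is never remeshed or smoothed after element removal; exported
  degraded surfaces are stair-stepped at the element scale.
* Factor transfer assumes the same material and degradation conditions and
  equal iteration granularity; large resolution mismatches between
  calibration and target meshes change the per-iteration meaning of a
  boundary layer.
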