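# Methods

This note records the model definitions, parameter choices, numerical
conventions and known limitations of the package. Energies are in units
of k_BT throughout (β = 1).

## Lattice model

The membrane is a periodic triangular lattice in axial coordinates: site
(q, r) with 0 ≤ q < W, 0 ≤ r < H, flattened to `r*W + q`, neighbours
(±1,0), (0,±1), (+1,−1), (−1,+1) modulo (W, H). Every site has six
distinct neighbours (enforced minimum box 3×4; H must additionally be
even) and the bond count is exactly 3·W·H. Rotations by multiples of 60°
are exact lattice automorphisms via cube-coordinate rotation
(x,y,z) → (−z,−x,−y), so rigid tile rotations introduce no rounding.

Spins s = +1 (L_d) and s = −1 (L_o) are conserved in number. For a
composition ratio r = n(−1)/n(+1) the minority count is
n(−1) = round(N·r/(1+r)), remainder to the majority phase; the default
r = 2/3 gives exact counts on boxes whose site number divides by 5.

### Hamiltonian

H = −J Σ_<ij> s_i s_j − Σ_a J_a s̃_a, with s̃_a the sum over the anchor's
host site and its six neighbours (odd, in [−7, 7]). The sign convention
is chosen so that a positive sT coupling favours L_d and a negative dC
coupling favours L_o, matching the measured partitioning preferences of
the two anchor chemistries; under it an anchor's bulk transfer free
energy between uniform phases is 14·J_a, which calibrates the couplings
from measured free energies as J_a = ΔG_p,Lo/14. Both published pairs
(1.9 → 0.136, −0.8 → −0.057) are reproduced by this single linear map.

Defaults: J = 0.55 (subcritical — the exact triangular-lattice critical
coupling is ln(3)/4 ≈ 0.2747, so the quench demixes), J_sT = 0.136,
J_dC = −0.057.

### Tiles

A tile is a rigid parallelogram block of sites (the axial image of the
~90 × 20 nm contact region of a Rothemund rectangular origami) with two
rows of anchors on opposite halves of the short axis, separated by
Δ = 16 nm by default — wider than the interface width ξ ≈ 8 nm, so each
anchor set can sit in its preferred phase when the tile straddles a
boundary. Designs 6×/12×/24× carry that many anchors of each type,
evenly spaced along the long edge; at coarse lattice resolutions two
neighbouring anchors may round onto the same site, in which case their
couplings simply add. The lattice resolution is configurable
(`nm_per_site`, default 2 nm → 45 × 10 sites per tile; the scaled-down
studies below use 4 nm → 22 × 5 sites). Footprints exclude each other
hard-core at all times.

Tile placement is random sequential insertion with uniform random origin
and orientation; the tile number is round(σ·N/footprint area). Insertion
failure after a configurable attempt budget raises an error naming the
achieved coverage.

## Monte Carlo dynamics

One cycle = N attempted nearest-neighbour spin exchanges (directed bonds
drawn uniformly) followed by one attempted rigid move per tile. This
definition is a package convention (it makes MC time roughly comparable
across box sizes). Exchanges are Kawasaki: unlike spins swap with
probability min(1, e^(−ΔE)); ΔE uses the local bonds plus a per-site
anchor field h (h_i = Σ of J_a over anchors whose star covers i),
maintained incrementally and verified against from-scratch rebuilds in
the tests. Tile proposals are a translation by one random lattice vector
or a rotation by ±60°, with equal probability; overlaps are rejected
outright, otherwise Metropolis on the anchor-energy change. Proposals
are symmetric, so detailed balance holds at the move level.

Quenches are instantaneous: a uniformly random spin field and tile
arrangement (the infinite-temperature state) is evolved directly at the
target couplings, with no annealing ramp. Tiles never desorb to bulk;
the only removal pathway is explicit mid-run deactivation (the
simulation analogue of fuel-strand-driven anchor displacement), which
deletes every tile at a stated cycle and lets the spin dynamics
continue. Three independent random streams (spin init, tile placement,
dynamics) derive from one seed, so deactivation at cycle 0 reproduces
the tileless run with the same seed exactly.

The inner loop is numba-compiled with a xorshift128+ generator seeded
via splitmix64 from numpy SeedSequence spawns; runs are bit-reproducible
per seed and replicate seeds are spawned deterministically from a base
seed. Throughput on one core is ~1×10⁸ attempted exchanges per second.

## Observables

- **Interface length L**: raw count of unlike-spin nearest-neighbour
  bonds. No smoothing of thermal interface roughness is applied; this
  affects absolute values, not design orderings. Note that one straight
  row-aligned interface cuts two bonds per column on the triangular
  lattice (a periodic stripe has L = 4W, not 2W).
- **Domain count**: connected components of the minority phase under the
  6-neighbour periodic adjacency; components below `min_size` (default
  10 sites, excluding single-spin thermal fluctuations) are reported
  separately and excluded from the count.
- **Tile at line**: a tile counts as at the line when ≥ 80% (inclusive)
  of its anchor contacts are favorable, a contact being one of the 7
  star sites of an anchor matching that anchor's preferred phase.
- **Line occupancy φ**: fraction of unlike bonds with at least one
  endpoint under any tile footprint (0 when L = 0). The exact
  experimental bookkeeping is not recoverable, so the occupancy rule is
  a strategy option: `any` (default) or `at_line` (count only tiles
  currently classified at the line). `any` includes a random-overlap
  baseline ≈ the covered-site fraction at early times.
- **Aggregation**: pointwise mean ± SEM (sample SD/√n; 0 for n = 1)
  over replicates aligned on identical recording cycles, plus
  domain-count histograms across replicates at chosen cycles.

## Line-adsorption model

Bulk tiles are a 2D lattice gas at coverage σ_b, chemical potential
ln(σ_b/(1−σ_b)). Line tiles are a 1D Tonks gas of hard rods of length
ℓ (the 90 nm long edge, lying along the boundary) confined to the ξ-wide
interface band, with binding free energy ΔG_line = n_dC·ΔG_dC (moving
the dC set into L_o from the tile's best bulk state in L_d, where the sT
set is already optimal). Equating chemical potentials:

ln(φ/(1−φ)) + φ/(1−φ) = ln(σ_b/(1−σ_b)) − ΔG_line − ln(a_tile/(ℓ·ξ))

The last term is the 2D↔1D standard-state mismatch; it makes the band
density equal the bulk density (K_p,int = 1) for an inert tile, as it
must. The overall coverage constraint (line-bound tiles count toward σ)
is closed self-consistently. K_p,int = band density / whole-surface
average density on a spherical vesicle (default R = 10 μm, line =
equator). Defaults: ξ = 8 nm, ℓ = 90 nm, a_tile = 90×60 nm².

Properties (verified numerically in the tests): φ ∈ [0,1), increasing
in σ and in |ΔG_line|; K_p,int → e^(−ΔG_line) as σ → 0 and decreases
with σ (saturation competition); design ordering φ(24×) > φ(12×) > φ(6×)
at fixed σ. With the defaults, φ(12×, σ = 0.30) = 0.836 — inside the
0.75–0.87 saturation band reported for the stabilization conditions.
Inversion of a measured K_p,int to σ uses bracketed root finding on the
monotone forward model, with error propagation from the measurement and
a ±25% ξ sensitivity band; saturation approaches 1 only slowly
(φ/(1−φ) ~ |ΔG_line|), which is the physical Tonks behaviour.

## Profile model and K_p,int estimation

A confocal line scan across the boundary is modelled as a blurred step
plus a Gaussian peak of the same width w:

I(x) = B_Ld + (B_Lo − B_Ld)·Φ((x−x₀)/w) + A·e^(−(x−x₀)²/(2w²))

This is the minimal form consistent with diffraction blurring of two
baselines and a line accumulation much narrower than the optics (ξ ≪ w);
the functional form is pluggable. Fitting is bounded nonlinear least
squares with a deterministic initialisation (baselines from the outer
quartiles, amplitude from max-minus-step, width from the FWHM of the
excess); non-convergence is flagged, never silently replaced, and a
near-zero amplitude raises a degenerate-peak flag.

K_p,int = (A·w·√(2π)/ξ + step(x₀)) / (f_Ld·B_Ld + f_Lo·B_Lo), intensity
taken proportional to tile surface density, f the phase area fractions
(default ½, ½). The estimator is invariant under global intensity
rescaling, and halving ξ doubles the peak contribution by construction.

## Synthetic data

Profile generation inverts the estimator: the amplitude realising a
target K_p,int is (K·avg − step)·ξ/(w√(2π)), so the noiseless profile
quantifies back to the target exactly. Noise is additive Gaussian
(default 5% of the L_d baseline, clipped at zero); the level is a
package choice, not a measured statistic. The default target is
K_p,int = 40: because ξ ≪ w, the amplitude is of order the baseline only
when K ~ w/ξ, and line-actant interfaces show partitioning of this
magnitude — smaller targets produce peaks buried in realistic noise.
Ring images place the same angular profile on a radially Gaussian ring
with two interface points π apart; sampling along the ring arc
reproduces the 1D generator. What the generators do *not* emulate:
photobleaching, 3D point-spread functions, vesicle-shape irregularities,
segmentation errors — recovery tests therefore validate the estimator,
not the microscopy pipeline.

## Scaled-down study conditions

The reference simulations (320×372 and 160×172 boxes, 2×10⁷ cycles, 15
replicates) are far beyond a desk budget; the package's statistical
checks run the same physics at reduced sizes chosen once:

- **Tileless coarsening**: 64×64, 10⁶ cycles, 15 replicates — every
  probe trajectory reaches a single minority domain by ~6×10⁵ cycles.
- **Design orderings**: 48×48 at 4 nm/site (six 22×5-site tiles at
  σ = 0.30), measured at 1.5×10⁵ cycles, when the tileless control is
  nearly fully coarsened. The coarser resolution keeps the physical tile
  (90×20 nm, Δ = 16 nm, same couplings and anchor spacing in nm) while
  fitting enough tiles in the box for pinning to operate; at 2 nm/site
  only ~5 tiles fit an affordable box and the interface-length ordering
  cannot be resolved. Mean over 15 replicates: L(24×) > L(12×) >
  L(6×) ≈ L(none) and φ(24×) > φ(12×) > φ(6×).
- **Deactivation**: the 24× design (strongest pinning), removal at 10⁵
  of 3×10⁵ cycles, 15 seed-paired replicates; the post-removal drop in L
  exceeds the tile-retaining control (one-sided paired t-test, α=0.05).

Passing at these scales demonstrates the orderings and limits, not the
absolute interface lengths or time constants of the full-scale system.

## Numerical choices and degenerate inputs

- Tile count and minority count round to nearest; ties follow Python's
  banker's rounding via `round`.
- φ ≡ 0 on a uniform field (L = 0); tiles-at-line fraction is NaN with
  zero tiles.
- Root finding (adsorption model) uses Brent bracketing at machine-level
  tolerances; infeasible inversions raise errors naming the attainable
  interval.
- The incremental anchor field accumulates float rounding over a run;
  agreement with rebuilds is asserted at 1e−9.
- Config validation (pydantic, extra keys forbidden) happens before any
  computation; an empty config reproduces the reference conditions.

## Known limitations

- No annealing between preparation and quench; no grand-canonical tile
  exchange; no cluster spin moves — coarsening kinetics are those of
  local Kawasaki dynamics only, and MC cycles do not map to physical
  time.
- The tile is a rigid parallelogram in lattice geometry; origami bending
  and membrane curvature are outside the model.
- The adsorption model treats tile–tile interactions at the line as pure
  1D hard-core exclusion and ignores orientational entropy corrections;
  its absolute φ and K_p,int values carry the standard-state choices
  documented above, while design orderings are robust to them.
- The profile machinery assumes an isolated, aligned interface crossing;
  it does not segment images or detect vesicles.
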