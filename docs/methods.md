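# Methods

`bltpgeom` quantifies the channel geometry of bridge-like lipid transfer
proteins (BLTPs) — very large rod-shaped proteins such as VPS13C whose
"taco shell" bridge domain carries a hydrophobic groove through which lipids
move between organelle membranes — and the buried surface of their
protein–protein interfaces.  This note records the model, the parameters
that matter, and the design choices made where the procedure was genuinely
open.

## Channel axis and slicing

The channel axis of an elongated atom selection is the first principal
component of the atom coordinates.  A straight axis is deliberate: the
measurement model is a stack of parallel clipping planes stepped along the
rod, not a curved centerline trace (HOLE-style pore tracing is a non-goal).
The direction's sign is fixed by an orientation rule — the atom with the
lowest residue number in the first chain sits at axial coordinate s ≈ 0 —
so profiles of different models are comparable N-terminus-first.  The axis
origin is placed so every selected atom has s ∈ [0, extent].

Atoms are partitioned into slabs of fixed thickness (default **5 Å**) as
half-open intervals [s_lo, s_hi), the final slab closed; the slab count is
⌈extent/thickness⌉ and every atom belongs to exactly one slab.  All slabs
share a single in-plane orthonormal basis (seeded deterministically from
the global axis least aligned with the channel direction), so successive
cross-sections are mutually registered like frames of a fixed camera.

Degenerate inputs: fewer than 3 atoms is an error; a near-isotropic cloud
(top two principal extents within 1%) logs a warning and applies a
deterministic lexicographic tie-break so repeated runs agree.

## Lumen cross-sections

Within a slab the projected atoms form a C-shaped wall.  A finite lumen
area requires closing the open mouth of the C; the default **mouth
closure** is the 2-D convex hull of the projected atom centers, which spans
the mouth with a chord and is exact on the synthetic fixtures.  An
alpha-shape closure (Delaunay triangles with circumradius < α, default
α = 8 Å) is available for strongly non-convex walls.

The slab plane is rasterized at `grid_resolution` (default **0.5 Å**;
0.25 Å roughly quadruples cost and is used where fixture tolerances
demand it) over the projected bounding box padded by 5 Å.  Cells inside
the closure boundary and outside every atom's projected vdW disk are lumen
cells; area = cell count × resolution².  A `--probe-inflate` option adds a
probe radius to the wall disks for a solvent-excluded-style lumen; the
default is bare vdW radii.

Two width metrics are emitted per slab, because "the channel is ~20 Å
across" can mean either clearance or rim-to-rim distance:

- **width_inscribed** — diameter of the largest circle inscribed in the
  lumen, computed from the Euclidean distance transform of the lumen mask
  (clearance).
- **width_maxchord** — maximum pairwise distance between lumen boundary
  cells (rim-to-rim).

Discretization accuracy: on analytic fixtures at 0.25 Å resolution, areas
are within 2% (in practice <0.1%), the inscribed width within one grid
cell.  A diameter derived by doubling a radius estimate (closed-ring
fixture) carries twice that, i.e. a two-cell tolerance.  Rasterization is
grid-aligned, so a rigid rotation of the input changes per-slab areas at
the sub-percent level while slab memberships and axial coordinates are
exactly invariant.

Slabs with fewer than 3 atoms yield an empty section (zero area and
widths), not an error, so end caps never abort a profile.

## Volume, capacity, and summary trimming

Lumen volume is the exact sum Σ areaᵢ·Δᵢ over slabs (Δ = slab height, the
last possibly shorter).  Lipid capacity = volume / `per_lipid_volume`,
with **1300 ų** as the default per-lipid molecular volume — a typical
glycerophospholipid volume in a bilayer; it is an explicit, logged divisor,
not a measured constant, and the capacity scales inversely with it.

Headline min/max widths exclude slabs whose atom count is below
`trim_fraction` (default **0.25**) of the median slab count: the tapering
cap regions at either end of a bridge domain would otherwise dominate the
minimum.

## SASA and buried surface

The Shrake–Rupley engine places `n_points` (default **960**) points on
each atom's probe-inflated sphere using the deterministic golden-spiral
(Fibonacci) lattice; a point is accessible when outside every neighbour's
inflated sphere (neighbours found via a KD-tree over atom centers).
Per-atom SASA = accessible fraction × 4π(r+probe)².  Probe radius default
**1.4 Å** (water); radii from a Bondi-type table (C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, H 1.20, default 1.70 Å).  With no RNG in the path, SASA
is bit-reproducible; quadrature error on an isolated sphere is < 0.5% at
960 points and halving stepwise with the point count.

Buried surface area between groups A and B is the **two-sided** sum
SASA(A) + SASA(B) − SASA(A∪B), matching the "total buried surface"
convention; the one-sided interface area (half of it) is always reported
alongside, since published interface numbers use both conventions.
Negative totals within quadrature noise on contact-free groups are clamped
to zero.

## Lining classification and hydropathy

An atom lines the channel when the 2-D segment from its slab's lumen
centroid to the atom's projected center is not blocked by any other
member's disk (line of sight).  One refinement over the bare rule: a disk
that already covers the target atom's center does not block — contiguous
wall atoms whose vdW spheres overlap are one surface, and without this
refinement every atom of a tightly packed wall would occlude its own
neighbours.  Atoms of empty slabs are unassigned.

Per-slab hydropathy means use the Kyte–Doolittle scale, residue-level
(each residue counts once per slab regardless of atom count); residues
outside the 20-residue table are excluded, and an empty class yields a
missing value, not zero.  On the two-layer Leu/Asp groove the lining mean
(3.8) exceeds the exterior mean (−3.5) in every interior slab — the
hydrophobic-channel signature.

## Synthetic structures

The generator emulates the geometry of a BLTP bridge domain, not its
chemistry: pseudo-atoms on a cylindrical lattice (arc and axial step =
`lattice_spacing`, default 1.5 Å) spanning the closed arc of the groove,
with a constant or flaring inner radius, 1..k wall layers spaced
`layer_spacing` apart, per-layer residue identities (default Leu inside /
Asp outside), optional seeded isotropic Gaussian jitter, and exact ground
truth (axis, per-position radius, analytic lumen area under the convex
closure, per-atom lining labels).  Sphere systems with closed-form surface
areas serve as SASA and interface fixtures.  What synthetic grooves do
*not* reproduce: real β-sheet backbone geometry, side-chain packing,
irregular wall thickness, and curvature of the bridge axis — so passing
the recovery tests validates the measurement chain, not the biology of
any particular deposited model.

Problem sizes are chosen so the full validation chain runs in seconds:
100 Å grooves (~1.5k–3.4k pseudo-atoms) for recovery and lining tests, a
300 Å groove (~7.6k atoms) for the full-length profile, ≤50-sphere
systems for SASA oracles.

## Full-scale worked example

The repository's end-to-end example is a 300 Å half-pipe groove whose
channel flares linearly from 20 Å across at the N-terminal end to 50 Å at
the C-terminal end — the published dimensions of the VPS13C bridge domain.
For this stand-in the lattice points mark the channel surface itself
(zero atom radius), so the rim-to-rim width metric reads the surface
dimensions directly.  Running the profile pipeline on it measures back the
extent (~300 Å), the width range (~20–50 Å), and, at the default
1300 ų/lipid, a capacity of ~119 lipids — each number computed by the
pipeline, none hard-coded.

Analysing a real deposited model (e.g. a VPS13 or ATG2 coordinate file
fetched separately) uses the same commands with a chain/residue selection
for the bridge domain; the tool itself never downloads.

## Known limitations

- Straight-axis assumption: a strongly bent rod shortens the apparent
  extent and mixes slabs near the bend.
- Convex mouth closure overestimates lumen area where the wall is locally
  concave inward; use the alpha closure there.
- Grid metrics carry one-cell discretization error; widths inherit grid
  alignment sensitivity under rotation (sub-percent on areas).
- SASA cost grows with atoms × points; ~25k-atom full-length models take
  minutes per evaluation at 960 points.
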