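# Methods

`microvillus` builds a coarse-grained structural model of the
microvillar actin core bundle and its brush-border context. This note
records the model, its assumptions, the parameters that matter, and
the numerical choices made where the design was genuinely open.

## The geometric model

**Helical symmetry.** An actin filament is generated from one monomer
by a screw operation: rise 27.57 Å and twist −166.154° per monomer
about the filament (z) axis. Thirteen monomers then complete six full
turns of the short-pitch helix (13/6 symmetry), so monomer *i* and
monomer *i* + 13 are rotationally equivalent; one 13-monomer *repeat*
(358.41 Å) is the periodic unit of everything placed on the bundle.
Closure detection accepts the smallest unit count whose accumulated
twist is within `closure_tolerance` of a whole number of turns. The
default tolerance is 0.01° of total residual: the printed twist value
−166.154° misses exact 13/6 closure by 0.002° over the repeat (13 ×
166.154 = 2160.002), which we treat as rounding noise, while a
genuinely incommensurate filament twist (−166.40°, 0.25°/monomer away
from 13/6) accumulates 3.25° and is correctly left open. Ideal 13/6
behaviour is the default; the incommensurate twist is available as an
override with no closure expected.

**Lattice and bundle.** Filaments sit on a centred hexagonal lattice
(spacing *a* = 120 Å; 2 rings → 19 filaments), unipolar and in axial
register: site (*f*, *i*) has the same z and the same azimuthal phase
on every filament. Monomer index increases toward the pointed (minus)
end; the canonical frame is pointed-up, and a single rigid flip
(`polarity="barbed-up"`) produces the in-situ orientation with barbed
ends apical. The three nearest-neighbour bond axes (0°/60°/120° mod
180°) are labelled d/e/f; the assignment of letters to axes is a fixed
convention, as the three directions are equivalent by symmetry.

**Hexagonal mismatch.** Embedding a 13/6 helix in a hexagonal lattice
frustrates cross-linking. A cross-link along bond direction θ needs a
monomer facing θ on one filament and a monomer facing θ + 180° on the
other; because all filaments twist in phase, the achievable facing
azimuths are the 13 multiples of the twist (spacing 360°/13 ≈ 27.69°
mod 360°). The best monomer pair leaves a total angular misfit of
dist(θ, A) + dist(θ+180°, A), which the two binding domains share
equally, giving the per-domain accommodation

    deviation(θ) = ½ · [dist(θ, A) + dist(θ + 180°, A)].

For 13/6 this is 360°/52 ≈ **6.92°** for *every* bond direction (180°
falls exactly mid-gap in the azimuth grid), the ±7° flexibility a
cross-linker must supply; for an ideal hexagonal 6/1 helix it is 0.
The undirected achievable axes (multiples of the twist mod 180°) are
180°/13 ≈ **13.85°** apart: flexibility beyond ±that spacing would
also admit the reciprocal, filament-swapped binding conformation, so
uniqueness of one cross-link per filament pair per repeat bounds the
flexibility from above. Worst-case deviation is defined over the
undirected pair {θ, θ+180°}; this two-sided definition is adopted
because it reproduces both bounds and the exact-zero mismatch of the
6/1 helix.

## Component placement

Components are defined once relative to a canonical monomer and
positioned by symmetry propagation: pose on site (*f*, *i*) =
site transform ∘ reference pose. Cross-linker selection applies, in
order: (1) both domains bound to the two filaments of one lattice
edge, with every bead projecting between the two filament axes
(relative tolerance 0.05 on the projection); (2) mean facing deviation
of the two domains within the hexagonal-mismatch bound (+0.01° slack
for round-off); (3) domain-anchor separation within the component's
linker reach; (4) the rank-1 domain (fimbrin ABD1, villin V1–6) bound
pointed-ward — at higher monomer index — of the rank-2 domain, which
is the hard filter that eliminates the reciprocal orientation;
(5) deterministic tie-break by lowest monomer index, then filament
order. On the default bundle this yields exactly one placement per
species per edge per complete repeat (partial top/bottom repeats stay
bare), all placements of one direction class at the same monomer
levels (the three vertical levels d/e/f, staggered by ~4 monomers
between classes), and fimbrin and villin on disjoint monomers.

**Surrogate geometry.** The EM-fitted atomic cross-link coordinates
this model descends from were never deposited, so the components are
parameterized sphere models carrying the placement *criteria* rather
than atomic detail; every number below is a spec-file parameter.

| component | geometry (defaults) |
|---|---|
| fimbrin | 2 ABD beads (r 13 Å) anchored 40 Å from their filament axes + 2 core beads; linker reach 55 Å; mass 70 kDa |
| villin | V1–6 arc of 6 beads (r 9 Å) at 35 Å + headpiece bead (r 8 Å) at 30 Å; linker reach 75 Å; binding interface rotated 3 × 360°/13 ≈ 83.1°; mass 92.5 kDa |
| Myo1A | motor bead (r 18 Å) at 45 Å; straight 140 Å neck at 80° to the filament axis (rigor lever, "nearly perpendicular"); 3 IQ frames at 0.25/0.55/0.85 of the neck; TH1 tail bead at the tip; radial reach ≥ 170 Å (bundle surface → membrane at ~500 Å from the axis) |
| calmodulin | one 12 Å bead per IQ frame; 16.7 kDa |

The villin azimuth offset models its binding surface on actin being
distinct from fimbrin's; any non-zero multiple of the 27.69° azimuth
grid step shifts villin to different monomers of the repeat, which is
what vertically staggers the two cross-linkers and keeps them
clash-free. Three grid steps centres villin between consecutive
fimbrin levels. The offset changes *which* monomers villin occupies,
not the count or the selection logic.

**Myosin.** Motors go only on outer-ring filaments, facing radially
outward. Per repeat per outer filament the two clash-free sites of
highest radial extension survive (`min_radial_extension` default
340 Å rejects the poorly oriented third-best site, whose extension
is ~344–400 Å depending on filament azimuth, while keeping it
available as a turn extra). Stepping to the azimuthally adjacent
outer filament advances the best-facing monomer by two indices — one
monomer along the two-start long-pitch helix — so the motors trace
barber-pole stripes with pitch 12 × 2 × 27.57 Å = 661.7 Å. One full
360° tour (24 monomers of z) falls one 27.69° azimuth-grid step short
of closing; the leftover site is assigned as a third myosin on the
seam filament (the outer filament at the tour's start azimuth, a
convention) once per turn: `floor(362/24) = 15` extras on the default
build. Note the stripe pitch (24 rises) is close to but not equal to
the long-pitch helix pitch of a single filament (26 rises); the 8%
difference is the same azimuth-grid mismatch that creates the seam.

**Barber-pole fit.** Because of the seam, no single coherent helix
threads all motors, and a global helical (periodogram) fit is
ill-posed. The pitch is instead estimated from the local stripe
slope: for each adjacent pair of outer filaments, the axial shift
that best maps one motor set onto the other (set correlation, robust
to the two strands sharing z levels), median across pairs. Strand
count is the number of phase classes of (z − slope·azimuth) modulo
one repeat length, ignoring classes holding < 10% of motors (the
seam extras). The default build gives 2 strands, right-handed.

**Steric validation.** Beads of distinct components clash when their
centre distance is below `overlap_factor × (r₁ + r₂)` with
`overlap_factor = 0.9` (soft core: coarse beads overestimate
envelopes). kd-tree accelerated; pairs within one component, and
motor–light-chain pairs bonded through an IQ frame, are exempt. The
saturated default build has zero fimbrin–villin clashes.

## Analytics

* **Saturation stoichiometry** = 10 × edges/(filaments × 13) per
  cross-linker species: 420/247 ≈ 1.70 per 10 actin for 19 filaments
  (measured: 1.3:10 fimbrin, 1.6:10 villin). Grows monotonically with
  ring count toward the interior limit 30/13 ≈ 2.31.
* **Packing density** (Matthews coefficient, Å³/Da): mass = actin +
  fimbrin + villin over one repeat, with literature masses 41.8/70/
  92.5 kDa (not part of the geometric model; echoed in every report).
  The volume convention behind the reference figure of 3.9 Å³/Da is
  not recoverable, so three conventions are always reported side by
  side — per-filament hexagonal cell (4.95), regular hexagon through
  the outer filament axes (3.13), and convex hull dilated by a 30 Å
  probe margin (4.09) — which bracket 3.9; the per-filament cell has
  a closed form used as an exact test.
* **Spectrin length from density**: junctions of a hexagonal network
  carry 3 tetramers each and own a cell of (√3/2)a²; 10⁵ tetramers on
  135 µm² give a = 68.4 nm, the ~70 nm functional tetramer length.
* **Turnover**: (length/rise)/rate; 1000 nm at 0.3 monomers/s →
  20.2 min.
* **Surface amplification**: (hex footprint + cylinder + hemispherical
  cap − cap footprint)/footprint; 115–120 nm spacing, 50 nm radius,
  1000 nm length → 27–29×. Cap included by default.
* **Inter-bundle gap** = centre spacing − bundle diameter; the
  support-function diameter of the 19-filament lattice with a 25–35 Å
  effective filament radius is ~48–55 nm depending on azimuth
  (default filament radius 30 Å), leaving 60–70 nm for the terminal
  web at 115–120 nm spacing.

## Scene

Scene geometry is in nm. The membrane is a triangulated cylinder plus
hemispherical cap (two leaflets 5 nm apart); mesh areas converge
quadratically to the closed forms (0.05% at default resolution).
Microvilli are hexagonally packed (default 7 at 120 nm) with
barbed-up bundle copies identical up to translation. The terminal web
lays 2 spectrin tetramers (configurable; the in-vivo count per
adjacent pair is not established) per adjacent bundle pair: 65 nm
end-to-end antiparallel double helices (pitch 13 nm, radius 3 nm —
chosen to give a smooth double helix at that length; both exposed as
parameters), centred in the inter-bundle gap, with a warning when the
gap falls below half the tetramer length.

## I/O and fixtures

gemmi handles PDB/mmCIF. Assemblies are written one chain per
component instance (base-36 chain ids; strict-PDB mode limited to 62
chains), beads as carbon pseudo-atoms with the radius in the B-factor
column. Superposition uses the proper-rotation least-squares fit
(scipy `Rotation.align_vectors`) on centred point sets, with
degenerate (n < 3 or collinear) inputs rejected. Synthetic fixtures
generate deterministic pseudo-atomic structures per component from an
explicit seed; they encode only topology (bead counts, domain
layout), not real atomic coordinates, and are labelled synthetic.

## What the defaults do and do not show

Test problem sizes: unit and property tests run on 2-repeat bundles
(75 nm) and 7-filament lattices where brute-force oracles are cheap;
the census checks run the full default build (19 filaments ×
362 monomers, 2268 cross-linkers, 663 motors, 1989 light chains,
~7 s). Passing tests show that the stated selection criteria produce
a unique, clash-free, correctly counted arrangement under ideal
geometry. They do not probe thermal twist variability, elastic
filament deformation, partial occupancy, villin's Ca²⁺ severing
switch, or membrane mechanics — all outside the model. The per-domain
flexibility figure assumes the angular misfit is shared equally
between the two binding domains; an asymmetric split would change the
per-domain number but not the placement, which depends only on the
total misfit.
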