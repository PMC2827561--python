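# microvillus

A paracrystalline actin-bundle model builder for the microvillar
cytoskeleton of the intestinal brush border.

Brush-border microvilli are ~1 µm finger-like membrane projections,
each supported by a core bundle of ~19 parallel actin filaments.
The bundle is paracrystalline: every filament keeps F-actin's 13/6
helical symmetry (rise 27.57 Å, twist −166.154° per monomer — 13
monomers per 6 turns of the short-pitch helix), all filaments are
unipolar, in precise axial register, and packed on a hexagonal
lattice with 12.0 nm centre-to-centre spacing. That symmetry fully
determines where the bundle's accessory proteins can go, and this
package turns those constraints into a generative model:

* **helix** — screw operators, 13/6 repeat-closure detection, and the
  hexagonal-mismatch analysis: a 13/6 helix in a hexagonal lattice
  forces cross-linkers to absorb a ±6.92° deviation from their ideal
  binding orientation, while the 13.85° spacing of achievable
  cross-link axes caps admissible flexibility below ±14° if the
  binding conformation per 13-monomer repeat is to stay unique;
* **lattice** — hexagonal filament arrays (3r² + 3r + 1 points),
  nearest-neighbour adjacency with the three bond direction classes
  d/e/f, and orientation-dependent bundle cross-sections;
* **assembly** — builds the unipolar, axially registered bundle and
  places components by symmetry propagation: one fimbrin and one
  villin cross-link per filament pair per repeat (selected by the
  between-filament, flexibility, linker-reach and polarity criteria;
  the reciprocal 180°-swapped orientation is filtered out), two
  membrane-tethering Myo1A motors per repeat per outer filament plus
  a third per 360° turn, three calmodulin light chains per motor, a
  barber-pole fit of the motor stripes, and kd-tree steric validation;
* **analytics** — the quantitative self-checks: saturation
  stoichiometry (1.70 per 10 actin), Matthews-coefficient packing
  density under three volume conventions, spectrin tetramer length
  from membrane density (~68 nm), treadmilling turnover (~20 min),
  brush-border surface amplification (~27–29×), inter-bundle gap;
* **structio** — PDB/mmCIF I/O (gemmi), rigid superposition, and
  deterministic synthetic component fixtures, so nothing needs to be
  downloaded;
* **scene** — the in-situ picture: membrane meshes, hexagonally
  packed barbed-up microvilli at 115–120 nm spacing, and a coarse
  spectrin terminal web of 65 nm tetramers;
* **cli** — `microvillus build | analyze | scene | fixtures`.

Components are coarse-grained sphere surrogates (parameterized via
YAML/JSON spec files); atomic structures can be substituted by
superposition where available. See `docs/methods.md` for the model
in full.

## Worked example

Build the default saturated core bundle (19 filaments, 1000 nm,
27 complete repeats):

```sh
$ microvillus build --out demo
{"fimbrin": 1134, "villin": 1134, "myo1a": 663, "calmodulin": 1989, "clashes": 0}
```

1134 = 42 filament pairs × 27 repeats for each cross-linker species:
with one cross-link of each species per pair per repeat, the
stoichiometry in `demo/report.json` is 1.70 per 10 actin for both
fimbrin and villin (predicted saturation; measured values are 1.3:10
and 1.6:10). The 663 motors are 2 per repeat on each of the 12 outer
filaments (648) plus one per 360° turn around the bundle (15), each
carrying 3 calmodulin light chains (1989); `"clashes": 0` is the
steric check that the vertically staggered fimbrin and villin
cross-links never collide. The report also records the motor
barber-pole fit — 2 strands, pitch 661.7 Å, right-handed — and the
orientation-dependent bundle diameter (47.6–54.0 nm), and
`demo/assembly.cif` holds the full coarse assembly, one chain per
component instance.

The calculators are available directly:

```sh
$ microvillus analyze mismatch 27.57 -- -166.154
{"units_per_repeat": 13, "turns_per_repeat": 6, "max_deviation_deg": 6.923, "uniqueness_spacing_deg": 13.846}
$ microvillus analyze turnover 1000 0.3
{"length_nm": 1000.0, "rise_A": 27.57, "rate_per_s": 0.3, "turnover_min": 20.15}
$ microvillus analyze spectrin 1e5 135
{"n_tetramers": 100000.0, "membrane_area_um2": 135.0, "tetramer_length_nm": 68.39}
```

— the ±7° flexibility demand and <±14° uniqueness bound, the ~20 min
whole-bundle turnover at 0.3 monomers/s, and the ~70 nm functional
spectrin tetramer length implied by 10⁵ tetramers on a 135 µm²
membrane.

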