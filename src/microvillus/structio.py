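"""Structure file I/O, least-squares superposition, and synthetic fixtures.

PDB/mmCIF reading and writing is delegated to gemmi; this module adds
the assembly-export conventions (one chain per placed component
instance, deterministic chain naming, bead radii stored in the
B-factor column) and a generator of deterministic pseudo-atomic
component structures, so that building and testing never require
downloaded coordinates.

The fixtures are *synthetic*: coarse stand-ins with the documented
topology of each component (e.g. villin: six-repeat arc + linker +
headpiece; myosin: motor + three-IQ neck + tail anchor), not real
atomic models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .components import (
    ACTIN_BEAD_CENTER,
    ACTIN_BEAD_RADIUS,
    ACTIN_MASS,
    Bead,
    BindingDomain,
    ComponentSpec,
    default_specs,
)
from .errors import ParameterError, StructureIOError
from .helix import RigidTransform

__all__ = [
    "BeadModel",
    "AssemblyModel",
    "read_structure",
    "write_structure",
    "write_assembly",
    "superpose",
    "make_fixture",
    "FIXTURE_COMPONENTS",
]

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class BeadModel:
    """Coarse sphere representation of one component (local frame, Å)."""

    component: str
    beads: Tuple[Bead, ...]

    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.beads])

    @property
    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.beads))


# ---------------------------------------------------------------------------
# reading / writing

def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in ("pdb", "mmcif", "cif"):
            raise ParameterError(f"unknown structure format {fmt!r}")
        return "pdb" if f == "pdb" else "mmcif"
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise ParameterError(
        f"cannot infer format from {path.name!r}; pass format='pdb' or 'mmcif'"
    )


def read_structure(path: Union[str, Path], fmt: Optional[str] = None) -> gemmi.Structure:
    """Read a PDB or mmCIF file into a gemmi Structure."""
    path = Path(path)
    kind = _detect_format(path, fmt)
    if not path.exists():
        raise StructureIOError(f"no such file: {path}")
    try:
        if kind == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureIOError(f"failed to parse {path}: {exc}") from exc
    if sum(len(ch) for model in st for ch in model) == 0:
        raise StructureIOError(f"{path}: no atoms parsed (empty or truncated file?)")
    st.setup_entities()
    return st


def write_structure(st: gemmi.Structure, path: Union[str, Path],
                    fmt: Optional[str] = None) -> None:
    path = Path(path)
    kind = _detect_format(path, fmt)
    if kind == "pdb":
        for model in st:
            for chain in model:
                if len(chain.name) > 2:
                    raise StructureIOError(
                        f"chain id {chain.name!r} too long for PDB; write mmCIF"
                    )
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


@dataclass
class AssemblyModel:
    """Placed components ready for export: (name, beads) per instance."""

    components: List[Tuple[str, List[tuple]]]  # (name, [(center, radius, label)])

    @classmethod
    def from_build(cls, bundle, placements: Sequence = (),
                   include_actin: bool = True) -> "AssemblyModel":
        comps: List[Tuple[str, List[tuple]]] = []
        if include_actin:
            for f in range(bundle.n_filaments):
                comps.append((f"actin_{f}", bundle.actin_beads(f)))
        for p in placements:
            comps.append((p.component.name, p.world_beads()))
        return cls(components=comps)

    def n_beads(self) -> int:
        return sum(len(b) for _, b in self.components)


def _chain_name(index: int, width: int) -> str:
    digits = []
    for _ in range(width):
        index, r = divmod(index, 36)
        digits.append(_B36[r])
    return "".join(reversed(digits))


def write_assembly(
    model: AssemblyModel,
    path: Union[str, Path],
    fmt: Optional[str] = None,
    strict_pdb: bool = False,
) -> None:
    """Export an assembly, one chain per component instance.

    Beads are written as pseudo-atoms (element C); the bead radius
    goes into the B-factor column so coarse models round-trip.  Chains
    are named deterministically in base-36 order of placement; strict
    PDB mode allows at most 62 single-character chains, beyond which
    an error points at mmCIF.
    """
    path = Path(path)
    if not model.components:
        raise ParameterError("refusing to write an empty assembly")
    kind = _detect_format(path, fmt)
    n = len(model.components)
    if kind == "pdb" and strict_pdb and n > 62:
        raise StructureIOError(
            f"{n} chains exceed the 62-chain strict-PDB limit; use mmCIF"
        )
    width = 1 if (kind == "pdb" and strict_pdb) else max(2, int(np.ceil(np.log(max(n, 2)) / np.log(36))))
    st = gemmi.Structure()
    st.name = "microvillus-assembly"
    gm = gemmi.Model("1")
    for idx, (name, beads) in enumerate(model.components):
        chain = gemmi.Chain(_B36[idx] if width == 1 else _chain_name(idx, width))
        res = gemmi.Residue()
        res.name = (name[:3] or "UNK").upper()
        res.seqid = gemmi.SeqId(1, " ")
        for k, (center, radius, label) in enumerate(beads):
            atom = gemmi.Atom()
            atom.name = (label or f"B{k}")[:4]
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, center))
            atom.occ = 1.0
            atom.b_iso = float(radius)
            atom.serial = 0
            res.add_atom(atom)
        chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    write_structure(st, path, kind)


# ---------------------------------------------------------------------------
# superposition

def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> Tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns the proper rigid transform carrying ``mobile`` onto
    ``reference`` and the post-fit RMSD (Å).  Requires n ≥ 3
    non-collinear pairs.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ParameterError("superpose needs two equal-shape (n, 3) point sets")
    n = len(mob)
    if n < 3:
        raise ParameterError(f"superposition needs >= 3 point pairs, got {n}")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - cm, ref - cr
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise ParameterError("degenerate (collinear) point set; rotation undefined")
    rot, _ = Rotation.align_vectors(b, a)
    rmat = rot.as_matrix()
    transform = RigidTransform(rmat, cr - rmat @ cm)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mob) - ref) ** 2, axis=1))))
    return transform, rmsd


# ---------------------------------------------------------------------------
# synthetic fixtures

FIXTURE_COMPONENTS = (
    "actin", "fimbrin", "villin", "myosin", "light_chain", "spectrin_repeat",
)

_SPEC_KEYS = {
    "fimbrin": "fimbrin",
    "villin": "villin",
    "myosin": "myo1a",
    "light_chain": "calmodulin",
    "spectrin_repeat": "spectrin_repeat",
}


def _actin_spec() -> ComponentSpec:
    dom = BindingDomain(
        "monomer",
        polarity_rank=1,
        radial_offset=ACTIN_BEAD_CENTER,
        beads=(Bead("ACT", (0.0, 0.0, 0.0), ACTIN_BEAD_RADIUS, ACTIN_MASS),),
    )
    return ComponentSpec(name="actin", role="strut", domains=(dom,), mass=ACTIN_MASS)


def _fixture_spec(component: str) -> ComponentSpec:
    if component == "actin":
        return _actin_spec()
    return default_specs()[_SPEC_KEYS[component]]


def _fixture_beads(spec: ComponentSpec) -> Tuple[Bead, ...]:
    """Component beads laid out in its own local frame (domains offset
    along x as they would straddle a 120 Å filament gap)."""
    beads: List[Bead] = []
    ranked = spec.domains_by_rank()
    for d_idx, dom in enumerate(ranked):
        # rank-1 anchor at the origin facing +x; a cross-linker's second
        # domain sits across the 120 Å filament gap facing back (−x)
        flip = -1.0 if (spec.role == "crosslinker" and d_idx == 1) else 1.0
        x0 = 0.0 if d_idx == 0 else 120.0 - ranked[0].radial_offset - dom.radial_offset
        for b in dom.beads:
            c = (x0 + flip * b.center[0], flip * b.center[1], b.center[2])
            beads.append(Bead(f"{dom.name}:{b.label}", c, b.radius, b.mass))
    if spec.role == "motor":
        d = spec.neck_direction
        for k, frac in enumerate(spec.iq_fractions):
            c = tuple(d * frac * spec.neck_length)
            beads.append(Bead(f"IQ{k + 1}", c, 6.0, 2_000.0))
        beads.append(Bead("TH1", tuple(d * 1.02 * spec.neck_length), 10.0, 14_000.0))
    return tuple(beads)


def make_fixture(
    component: str, seed: int = 0
) -> Tuple[gemmi.Structure, BeadModel, ComponentSpec]:
    """Deterministic synthetic pseudo-atomic fixture for one component.

    Returns ``(structure, bead_model, spec)``.  The structure scatters
    a fixed number of pseudo-atoms inside each bead (one chain per
    bead); identical ``(component, seed)`` gives identical output.
    """
    if component not in FIXTURE_COMPONENTS:
        raise ParameterError(
            f"unknown component {component!r}; choose from {FIXTURE_COMPONENTS}"
        )
    spec = _fixture_spec(component)
    beads = _fixture_beads(spec)
    bead_model = BeadModel(component=component, beads=beads)

    rng = np.random.default_rng([seed, len(component), sum(map(ord, component))])
    st = gemmi.Structure()
    st.name = f"synthetic-{component}"
    gm = gemmi.Model("1")
    for b_idx, bead in enumerate(beads):
        chain = gemmi.Chain(_chain_name(b_idx, 2))
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(b_idx + 1, " ")
        n_atoms = max(4, int(bead.radius))
        # uniform points inside the bead, deterministically
        pts = rng.normal(size=(n_atoms, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= bead.radius * 0.7 * rng.random((n_atoms, 1)) ** (1.0 / 3.0)
        for a_idx in range(n_atoms):
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*(np.array(bead.center) + pts[a_idx]))
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st, bead_model, spec
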