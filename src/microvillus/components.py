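"""Parameterized coarse-grained component specifications.

Each bundle-associated protein (cross-linker, motor, light chain) is
described by a :class:`ComponentSpec`: one or two actin-binding
domains, each a small set of spheres ("beads") in a local frame, plus
the constraints the placement machinery enforces (linker reach,
polarity order of the domains along the filament axis).

The default specs below are *surrogate* geometries: coarse sphere
models whose dimensions are set by the component's known topology and
by the bundle geometry they must span (120 Å filament spacing,
~30 Å filament radius, membrane at ~500 Å from the bundle axis).  The
EM-fitted atomic cross-link coordinates they stand in for were never
deposited, so the surrogates carry the *criteria* (two domains between
the filaments, polarity order, reach) rather than atomic detail.  All
numbers are tunable, and specs round-trip through YAML/JSON.

Domain local frame convention: the domain anchor sits at the origin,
+x points away from the bound filament's axis (toward the partner
filament for a cross-linker, radially outward for a motor), +z is the
filament axis.  The anchor is placed ``radial_offset`` Å from the
bound filament's axis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .errors import ParameterError

__all__ = [
    "Bead",
    "BindingDomain",
    "ComponentSpec",
    "fimbrin_spec",
    "villin_spec",
    "myosin_spec",
    "light_chain_spec",
    "spectrin_repeat_spec",
    "default_specs",
    "load_spec",
    "save_spec",
    "ACTIN_BEAD_CENTER",
    "ACTIN_BEAD_RADIUS",
    "ACTIN_MASS",
    "FILAMENT_RADIUS",
]

#: Effective F-actin filament radius used for sterics and cross-sections (Å).
FILAMENT_RADIUS = 30.0

#: Coarse one-bead actin monomer: centre offset from the filament axis
#: toward the monomer's facing azimuth, and bead radius (Å).  The
#: envelope (offset + radius) matches the filament radius.
ACTIN_BEAD_CENTER = 8.0
ACTIN_BEAD_RADIUS = 22.0
ACTIN_MASS = 41_800.0  # Da

#: Azimuthal grid step of a 13/6 helix, degrees (360/13).
_GRID_STEP = 360.0 / 13.0


@dataclass(frozen=True)
class Bead:
    """Sphere in a domain-local frame (Å, Da)."""

    label: str
    center: tuple[float, float, float]
    radius: float
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"bead radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class BindingDomain:
    """One actin-binding domain of a component.

    ``polarity_rank`` orders domains along the filament axis: rank 1
    binds nearer the pointed (minus) end than rank 2, the selection
    rule that eliminates the reciprocal (filament-swapped) cross-link
    orientation.
    """

    name: str
    polarity_rank: int
    radial_offset: float
    beads: tuple[Bead, ...]


@dataclass(frozen=True)
class ComponentSpec:
    """A cross-linker, motor, or light chain as a placeable rigid body.

    ``binding_azimuth_offset`` (degrees) rotates the domain's binding
    interface relative to the monomer's facing azimuth: components with
    disparate binding surfaces on actin select different monomers
    within a repeat, which is what vertically staggers fimbrin and
    villin cross-links on the same filament pair.

    Motor extras: a straight neck of length ``neck_length`` leaves the
    motor domain at ``lever_angle`` degrees from the filament axis
    (≈80° in the rigor state, the near-perpendicular lever of Myo1A)
    and carries ``n_light_chain_sites`` IQ attachment frames at
    ``iq_fractions`` of the neck length.
    """

    name: str
    role: str  # "crosslinker" | "motor" | "light_chain" | "strut"
    domains: tuple[BindingDomain, ...]
    linker_max_separation: Optional[float] = None
    binding_azimuth_offset: float = 0.0
    neck_length: float = 0.0
    lever_angle: float = 80.0
    n_light_chain_sites: int = 0
    iq_fractions: tuple[float, ...] = ()
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("crosslinker", "motor", "light_chain", "strut"):
            raise ParameterError(f"unknown component role {self.role!r}")
        if self.role == "crosslinker":
            if len(self.domains) != 2:
                raise ParameterError(
                    f"cross-linker {self.name!r} must have exactly 2 "
                    f"actin-binding domains, got {len(self.domains)}"
                )
            if self.linker_max_separation is None or self.linker_max_separation < 0:
                raise ParameterError(
                    f"cross-linker {self.name!r} needs a nonnegative "
                    "linker_max_separation"
                )
        if self.role == "motor":
            if len(self.domains) != 1:
                raise ParameterError("motor specs have exactly 1 actin-binding domain")
            if self.n_light_chain_sites != len(self.iq_fractions):
                raise ParameterError("one IQ fraction per light-chain site required")
        ranks = [d.polarity_rank for d in self.domains]
        if len(set(ranks)) != len(ranks):
            raise ParameterError("polarity ranks must form a total order")

    def domains_by_rank(self) -> tuple[BindingDomain, ...]:
        return tuple(sorted(self.domains, key=lambda d: d.polarity_rank))

    @property
    def neck_direction(self) -> np.ndarray:
        """Unit neck direction in the domain-local frame (x outward, z axial)."""
        lam = np.deg2rad(self.lever_angle)
        return np.array([np.sin(lam), 0.0, np.cos(lam)])

    def radial_reach(self) -> float:
        """Maximum radial extent from the bound filament's axis (Å)."""
        reach = max(
            (d.radial_offset + b.center[0] + b.radius)
            for d in self.domains
            for b in d.beads
        )
        if self.role == "motor":
            tip = self.domains[0].radial_offset + self.neck_length * float(
                self.neck_direction[0]
            )
            reach = max(reach, tip)
        return reach


def _beads(raw: Sequence[tuple]) -> tuple[Bead, ...]:
    return tuple(Bead(label, tuple(map(float, c)), r, m) for label, c, r, m in raw)


def fimbrin_spec() -> ComponentSpec:
    """Surrogate fimbrin: compact tandem-ABD cross-linker.

    Two actin-binding-domain beads whose anchors sit 40 Å out from
    their filament axes (so they bridge the central 40 Å of the 120 Å
    gap), each backed by a core bead; ABD1 binds pointed-ward of ABD2.
    """
    abd1 = BindingDomain(
        "ABD1",
        polarity_rank=1,
        radial_offset=40.0,
        beads=_beads([("ABD1", (0.0, 0.0, 0.0), 13.0, 17_000.0),
                      ("core1", (10.0, 0.0, 4.0), 10.0, 18_000.0)]),
    )
    abd2 = BindingDomain(
        "ABD2",
        polarity_rank=2,
        radial_offset=40.0,
        beads=_beads([("ABD2", (0.0, 0.0, 0.0), 13.0, 17_000.0),
                      ("core2", (10.0, 0.0, -4.0), 10.0, 18_000.0)]),
    )
    return ComponentSpec(
        name="fimbrin",
        role="crosslinker",
        domains=(abd1, abd2),
        linker_max_separation=55.0,
        mass=70_000.0,
    )


def villin_spec() -> ComponentSpec:
    """Surrogate villin: gelsolin-like V1–6 core + headpiece.

    The six-repeat V1–6 core (rank 1, pointed-ward) is a small arc of
    six beads; the C-terminal headpiece is a single bead; the
    unstructured linker joining them is modelled only as a maximum
    anchor separation.  The binding interface is rotated three
    azimuthal grid steps (3 × 360°/13) from fimbrin's, so villin
    selects different monomers within each repeat and the two
    cross-linkers are vertically staggered rather than competing.
    """
    arc = []
    for k in range(6):
        ang = np.deg2rad(-50.0 + 20.0 * k)
        arc.append(
            (f"V{k + 1}", (6.0 * np.cos(ang), 16.0 * np.sin(ang), 0.0), 9.0, 12_250.0)
        )
    v16 = BindingDomain("V1-6", polarity_rank=1, radial_offset=35.0, beads=_beads(arc))
    hp = BindingDomain(
        "headpiece",
        polarity_rank=2,
        radial_offset=30.0,
        beads=_beads([("HP", (0.0, 0.0, 0.0), 8.0, 9_000.0)]),
    )
    return ComponentSpec(
        name="villin",
        role="crosslinker",
        domains=(v16, hp),
        linker_max_separation=75.0,
        binding_azimuth_offset=3.0 * _GRID_STEP,
        mass=92_500.0,
    )


def myosin_spec() -> ComponentSpec:
    """Surrogate Myo1A: motor domain + 3-IQ lever + membrane-binding tail.

    The neck leaves the motor at 80° to the filament axis (rigor lever,
    nearly perpendicular) and is long enough that the tail tip reaches
    ≥170 Å from the bound filament's axis — the reach needed to span
    from the core-bundle surface to a membrane at ~500 Å from the
    bundle axis.
    """
    motor = BindingDomain(
        "motor",
        polarity_rank=1,
        radial_offset=45.0,
        beads=_beads([("motor", (0.0, 0.0, 0.0), 18.0, 80_000.0)]),
    )
    return ComponentSpec(
        name="myo1a",
        role="motor",
        domains=(motor,),
        neck_length=140.0,
        lever_angle=80.0,
        n_light_chain_sites=3,
        iq_fractions=(0.25, 0.55, 0.85),
        mass=110_000.0,
    )


def light_chain_spec() -> ComponentSpec:
    """Calmodulin light chain: one bead clamped around an IQ site."""
    dom = BindingDomain(
        "calmodulin",
        polarity_rank=1,
        radial_offset=0.0,
        beads=_beads([("CaM", (0.0, 0.0, 0.0), 12.0, 16_700.0)]),
    )
    return ComponentSpec(name="calmodulin", role="light_chain", domains=(dom,),
                         mass=16_700.0)


def spectrin_repeat_spec() -> ComponentSpec:
    """One spectrin repeat as a strut bead (terminal-web coarse model)."""
    dom = BindingDomain(
        "repeat",
        polarity_rank=1,
        radial_offset=0.0,
        beads=_beads([("SPC", (0.0, 0.0, 0.0), 12.0, 12_000.0)]),
    )
    return ComponentSpec(name="spectrin_repeat", role="strut", domains=(dom,),
                         mass=12_000.0)


def default_specs() -> dict[str, ComponentSpec]:
    return {
        "fimbrin": fimbrin_spec(),
        "villin": villin_spec(),
        "myo1a": myosin_spec(),
        "calmodulin": light_chain_spec(),
        "spectrin_repeat": spectrin_repeat_spec(),
    }


# ---------------------------------------------------------------------------
# serialization (YAML / JSON, shared schema)

def spec_to_dict(spec: ComponentSpec) -> dict:
    d = asdict(spec)
    d["schema"] = "microvillus/component-spec/1"
    return d


def _spec_from_dict(d: dict) -> ComponentSpec:
    d = dict(d)
    d.pop("schema", None)
    try:
        domains = tuple(
            BindingDomain(
                name=dd["name"],
                polarity_rank=int(dd["polarity_rank"]),
                radial_offset=float(dd["radial_offset"]),
                beads=tuple(
                    Bead(b["label"], tuple(map(float, b["center"])),
                         float(b["radius"]), float(b.get("mass", 0.0)))
                    for b in dd["beads"]
                ),
            )
            for dd in d.pop("domains")
        )
        return ComponentSpec(
            domains=domains,
            iq_fractions=tuple(d.pop("iq_fractions", ()) or ()),
            **d,
        )
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"malformed component spec: {exc}") from exc


def save_spec(spec: ComponentSpec, path: Union[str, Path]) -> None:
    path = Path(path)
    data = spec_to_dict(spec)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_spec(path: Union[str, Path]) -> ComponentSpec:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: not a component spec mapping")
    return _spec_from_dict(data)
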