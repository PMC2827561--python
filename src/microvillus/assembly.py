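"""Core-bundle construction and rigid-body placement by symmetry propagation.

The bundle is built once from the helical symmetry and the hexagonal
lattice: every monomer site (filament ``f``, index ``i``) carries the
rigid transform ``lattice-translation ∘ screw(i)``.  Components are
defined once relative to a canonical monomer and positioned on any
site by applying that site's transform (symmetry propagation), so the
whole assembly is generated from a handful of reference poses.

Cross-linker selection implements the placement criteria that make
the arrangement unique:

* the two actin-binding domains bind the two filaments of one edge and
  lie between their axes;
* the monomers bound must face each other: the angular misfit, split
  over the two domains, must stay within the flexibility bound set by
  the hexagonal mismatch of the helix (±6.92° for 13/6 actin);
* the unstructured-linker reach caps the domain separation;
* the rank-1 domain binds pointed-ward of the rank-2 domain, which
  rejects the reciprocal (filament-swapped) orientation;
* remaining ties break deterministically (lowest monomer index, then
  filament order).

Myosin motors go on outer-ring filaments only, facing radially
outward, keeping per repeat the two clash-free sites of highest
radial extension plus one extra site per 360° turn about the bundle
on a single "seam" filament — the filament where the one-monomer-step-
per-filament barber-pole path fails to close after a full tour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .components import (
    ACTIN_BEAD_CENTER,
    ACTIN_BEAD_RADIUS,
    ACTIN_MASS,
    FILAMENT_RADIUS,
    Bead,
    BindingDomain,
    ComponentSpec,
)
from .errors import (
    InsufficientDataError,
    ParameterError,
    PlacementError,
)
from .helix import (
    HelicalSymmetry,
    RigidTransform,
    circular_distance,
    hexagonal_mismatch,
    monomer_transform,
)
from .lattice import Edge, HexLattice

logger = logging.getLogger(__name__)

__all__ = [
    "Bundle",
    "DomainPlacement",
    "Placement",
    "MotorPlacementSet",
    "Clash",
    "build_bundle",
    "propagate_pose",
    "enumerate_crosslink_candidates",
    "select_crosslink",
    "place_all_crosslinkers",
    "place_myosin",
    "attach_light_chains",
    "barber_pole_parameters",
    "detect_clashes",
]


@dataclass
class Bundle:
    """Unipolar, axially registered filament bundle.

    Monomer index increases toward the pointed (minus) end.  In the
    canonical ``pointed-up`` polarity, index i sits at z = i × rise; a
    ``barbed-up`` bundle is the same assembly flipped rigidly about
    the x axis (the in-situ orientation, barbed ends apical).
    """

    symmetry: HelicalSymmetry
    lattice: HexLattice
    monomers_per_filament: int
    polarity: str = "pointed-up"

    def __post_init__(self) -> None:
        if self.polarity not in ("pointed-up", "barbed-up"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")

    @property
    def n_filaments(self) -> int:
        return len(self.lattice)

    @property
    def n_sites(self) -> int:
        return self.n_filaments * self.monomers_per_filament

    @property
    def n_repeats(self) -> int:
        """Number of complete symmetry repeats per filament."""
        u = self.symmetry.units_per_repeat
        return 0 if u is None else self.monomers_per_filament // u

    @property
    def base_transform(self) -> RigidTransform:
        if self.polarity == "barbed-up":
            return RigidTransform.about_x(180.0)
        return RigidTransform.identity()

    def site_transform(self, filament: int, i: int) -> RigidTransform:
        """World transform of monomer site (filament, i)."""
        if not (0 <= filament < self.n_filaments):
            raise IndexError(f"filament {filament} out of range")
        if not (0 <= i < self.monomers_per_filament):
            raise IndexError(f"monomer index {i} out of range")
        x, y = self.lattice.points[filament]
        shift = RigidTransform.from_translation([x, y, 0.0])
        return self.base_transform @ shift @ monomer_transform(self.symmetry, i)

    def monomer_azimuth(self, i: int, offset: float = 0.0) -> float:
        """Facing azimuth (degrees, canonical frame) of monomer index i."""
        return (i * self.symmetry.twist + offset) % 360.0

    def actin_beads(self, filament: int) -> List[tuple[np.ndarray, float, str]]:
        """Coarse one-bead-per-monomer representation of one filament."""
        out = []
        for i in range(self.monomers_per_filament):
            t = self.site_transform(filament, i)
            c = t.apply(np.array([ACTIN_BEAD_CENTER, 0.0, 0.0]))
            out.append((c, ACTIN_BEAD_RADIUS, "ACT"))
        return out


def build_bundle(
    sym: HelicalSymmetry,
    lattice: HexLattice,
    length_nm: float,
    polarity: str = "pointed-up",
) -> Bundle:
    """Build a bundle of the given axial length (nm; internal units Å)."""
    if length_nm <= 0:
        raise ParameterError(f"length must be positive, got {length_nm}")
    if len(lattice) == 0:
        raise ParameterError("lattice has no filaments")
    monomers = int(np.floor(length_nm * 10.0 / sym.rise))
    if monomers < 1:
        raise ParameterError("bundle shorter than one monomer rise")
    return Bundle(
        symmetry=sym,
        lattice=lattice,
        monomers_per_filament=monomers,
        polarity=polarity,
    )


def propagate_pose(
    reference_pose: RigidTransform, bundle: Bundle, filament: int, i: int
) -> RigidTransform:
    """Position a pose defined on the canonical monomer onto site (f, i)."""
    return bundle.site_transform(filament, i) @ reference_pose


# ---------------------------------------------------------------------------
# placements

@dataclass
class DomainPlacement:
    """One binding domain resolved onto a monomer site."""

    domain: BindingDomain
    filament: int
    monomer: int
    transform: RigidTransform  # world pose of the domain frame
    deviation: float = 0.0  # angular accommodation of this domain (deg)


_NECK_BEAD_RADIUS = 6.0
_TAIL_BEAD_RADIUS = 10.0


@dataclass
class Placement:
    """A component instance positioned in the bundle."""

    component: ComponentSpec
    domains: List[DomainPlacement]
    edge: Optional[Edge] = None
    level_class: Optional[str] = None  # d | e | f for cross-linkers
    repeat_index: Optional[int] = None
    parent: Optional["Placement"] = None  # bonded parent (motor of a light chain)
    extra: dict = field(default_factory=dict)

    def world_beads(self) -> List[tuple[np.ndarray, float, str]]:
        """All beads of this instance in world coordinates."""
        beads: List[tuple[np.ndarray, float, str]] = []
        for dp in self.domains:
            for b in dp.domain.beads:
                beads.append((dp.transform.apply(np.array(b.center)), b.radius, b.label))
        if self.component.role == "motor":
            t = self.domains[0].transform
            d = self.component.neck_direction
            length = self.component.neck_length
            for k, frac in enumerate(self.component.iq_fractions):
                beads.append((t.apply(d * frac * length), _NECK_BEAD_RADIUS, f"NK{k+1}"))
            beads.append((t.apply(d * 1.02 * length), _TAIL_BEAD_RADIUS, "TH1"))
        return beads

    def light_chain_frames(self) -> List[RigidTransform]:
        if self.component.role != "motor":
            raise ParameterError("light-chain frames exist only on motor placements")
        t = self.domains[0].transform
        d = self.component.neck_direction
        length = self.component.neck_length
        return [
            t @ RigidTransform.from_translation(d * frac * length)
            for frac in self.component.iq_fractions
        ]

    def bound_sites(self) -> List[tuple[int, int]]:
        return [(dp.filament, dp.monomer) for dp in self.domains]


def _bond_angle(lattice: HexLattice, a: int, b: int) -> float:
    dx, dy = lattice.points[b] - lattice.points[a]
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def _domain_world(
    bundle: Bundle, spec: ComponentSpec, dom: BindingDomain, f: int, i: int
) -> RigidTransform:
    ref = RigidTransform.about_z(spec.binding_azimuth_offset) @ (
        RigidTransform.from_translation([dom.radial_offset, 0.0, 0.0])
    )
    return propagate_pose(ref, bundle, f, i)


def enumerate_crosslink_candidates(
    bundle: Bundle,
    spec: ComponentSpec,
    edge: Edge,
    repeat_index: int,
    flexibility: Optional[float] = None,
    between_tolerance: float = 0.05,
) -> List[Placement]:
    """All admissible (monomer-pair, domain-assignment) cross-link candidates.

    A candidate binds domain ranks (1, 2) onto monomers (i, j) of the
    edge's two filaments, in either assignment order, subject to:

    * facing: the mean angular deviation of the two domains from their
      bond directions is within ``flexibility`` (default: the
      hexagonal-mismatch bound of the bundle's symmetry, ±6.92° for
      13/6, with a small numerical slack);
    * reach: domain anchors within ``linker_max_separation``;
    * betweenness: every bead projects onto the open segment between
      the two filament axes (relative tolerance on the projection).

    Repeats that are not complete (fewer than units_per_repeat
    monomers remaining) yield no candidates.
    """
    sym = bundle.symmetry
    u = sym.units_per_repeat
    if u is None:
        raise ParameterError("cross-link placement requires a closed symmetry")
    lo = repeat_index * u
    hi = lo + u
    if lo < 0 or hi > bundle.monomers_per_filament:
        logger.info(
            "repeat %d incomplete on edge (%d,%d); skipped",
            repeat_index, edge.i, edge.j,
        )
        return []
    if flexibility is None:
        flexibility = hexagonal_mismatch(sym)[0] + 0.01

    beta = spec.binding_azimuth_offset
    d1, d2 = spec.domains_by_rank()
    pa = bundle.lattice.points[edge.i]
    pb = bundle.lattice.points[edge.j]
    span = pb - pa
    span2 = float(span @ span)

    candidates: List[Placement] = []
    for fa, fb in ((edge.i, edge.j), (edge.j, edge.i)):
        th_ab = _bond_angle(bundle.lattice, fa, fb)
        th_ba = (th_ab + 180.0) % 360.0
        for i in range(lo, hi):
            dev1 = circular_distance(bundle.monomer_azimuth(i, beta), th_ab)
            for j in range(lo, hi):
                dev2 = circular_distance(bundle.monomer_azimuth(j, beta), th_ba)
                if 0.5 * (dev1 + dev2) > flexibility + 1e-9:
                    continue
                t1 = _domain_world(bundle, spec, d1, fa, i)
                t2 = _domain_world(bundle, spec, d2, fb, j)
                if (
                    np.linalg.norm(t1.translation - t2.translation)
                    > spec.linker_max_separation
                ):
                    continue
                ok = True
                for dp_t, dom in ((t1, d1), (t2, d2)):
                    for b in dom.beads:
                        w = dp_t.apply(np.array(b.center))
                        frac = float((w[:2] - pa) @ span) / span2
                        if not (-between_tolerance <= frac <= 1.0 + between_tolerance):
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    continue
                candidates.append(
                    Placement(
                        component=spec,
                        domains=[
                            DomainPlacement(d1, fa, i, t1, dev1),
                            DomainPlacement(d2, fb, j, t2, dev2),
                        ],
                        edge=edge,
                        level_class=edge.direction_class,
                        repeat_index=repeat_index,
                    )
                )
    return candidates


def select_crosslink(candidates: Sequence[Placement], spec: ComponentSpec) -> Placement:
    """Pick the unique cross-link from a candidate list.

    Hard filter: the rank-1 domain must bind pointed-ward (higher
    monomer index) of the rank-2 domain — the polarity criterion that
    eliminates the reciprocal 180°-swapped orientation.  Survivors are
    ordered by (lowest monomer index, filament ids, monomer ids) and
    the first is returned.
    """
    if not candidates:
        raise PlacementError(f"no cross-link candidates for {spec.name}")
    survivors = []
    for c in candidates:
        by_rank = sorted(c.domains, key=lambda dp: dp.domain.polarity_rank)
        if all(
            by_rank[k].monomer > by_rank[k + 1].monomer
            for k in range(len(by_rank) - 1)
        ):
            survivors.append(c)
    if not survivors:
        ref = candidates[0]
        raise PlacementError(
            f"{spec.name}: all candidates on edge ({ref.edge.i},{ref.edge.j}) "
            f"repeat {ref.repeat_index} violate the polarity order"
        )
    survivors.sort(
        key=lambda c: (
            min(dp.monomer for dp in c.domains),
            tuple(dp.filament for dp in c.domains),
            tuple(dp.monomer for dp in c.domains),
        )
    )
    return survivors[0]


def place_all_crosslinkers(
    bundle: Bundle,
    fimbrin: ComponentSpec,
    villin: ComponentSpec,
    edges: Optional[Sequence[Edge]] = None,
) -> List[Placement]:
    """One fimbrin and one villin per edge per complete repeat."""
    from .lattice import adjacency_edges

    if edges is None:
        edges = adjacency_edges(bundle.lattice)
    placements: List[Placement] = []
    for spec in (fimbrin, villin):
        for e_idx, edge in enumerate(edges):
            for r in range(bundle.n_repeats):
                cands = enumerate_crosslink_candidates(bundle, spec, edge, r)
                chosen = select_crosslink(cands, spec)
                chosen.extra["edge_index"] = e_idx
                placements.append(chosen)
    return placements


# ---------------------------------------------------------------------------
# myosin

@dataclass
class MotorPlacementSet:
    """Motor placements plus the bookkeeping the selection produced."""

    placements: List[Placement]
    skipped: List[tuple[int, int]]  # (filament, repeat) with no clash-free site
    turn_monomers: int  # axial monomers per 360° tour of the outer ring
    n_outer: int

    def __iter__(self):
        return iter(self.placements)

    def __len__(self) -> int:
        return len(self.placements)


def _motor_candidate(
    bundle: Bundle, spec: ComponentSpec, f: int, k: int
) -> Placement:
    dom = spec.domains[0]
    t = _domain_world(bundle, spec, dom, f, k)
    tip = t.apply(spec.neck_direction * spec.neck_length)
    p = Placement(
        component=spec,
        domains=[DomainPlacement(dom, f, k, t)],
        extra={"tip": tip, "radial_extension": float(np.linalg.norm(tip[:2]))},
    )
    return p


def _clash_free(
    bundle: Bundle,
    placement: Placement,
    f: int,
    obstacle_tree: Optional[cKDTree],
    obstacle_radii: Optional[np.ndarray],
    overlap_factor: float,
) -> bool:
    pts = bundle.lattice.points
    others = np.delete(np.arange(len(pts)), f)
    for center, radius, _ in placement.world_beads():
        d2d = np.linalg.norm(pts[others] - center[:2], axis=1)
        if np.any(d2d < overlap_factor * (radius + FILAMENT_RADIUS)):
            return False
        if obstacle_tree is not None:
            rmax = float(obstacle_radii.max())
            idx = obstacle_tree.query_ball_point(
                center, overlap_factor * (radius + rmax)
            )
            for m in idx:
                if np.linalg.norm(obstacle_tree.data[m] - center) < overlap_factor * (
                    radius + obstacle_radii[m]
                ):
                    return False
    return True


def place_myosin(
    bundle: Bundle,
    motor_spec: ComponentSpec,
    min_radial_extension: float = 340.0,
    crosslinkers: Optional[Sequence[Placement]] = None,
    overlap_factor: float = 0.9,
) -> MotorPlacementSet:
    """Place membrane-tethering motors on the outer-ring filaments.

    Per repeat per outer filament the two clash-free, outward-facing
    sites of highest radial extension are kept.  Moving one filament
    around the outer ring advances the best-facing monomer by a fixed
    index step (one monomer along the long-pitch helix: two indices
    for 13/6 with 12 outer filaments), so these motors trace a
    barber-pole path; one full tour falls short of closure by one
    azimuthal grid step, and the leftover site is assigned as a third
    motor on the seam filament (outer filament at the tour's start
    azimuth) once per 360° turn.
    """
    if bundle.lattice.n_rings < 1:
        raise ParameterError("motor placement needs at least one lattice ring")
    sym = bundle.symmetry
    u = sym.units_per_repeat
    if u is None:
        raise ParameterError("motor placement requires a closed symmetry")
    outer = bundle.lattice.outer_indices()
    n_outer = len(outer)

    obstacle_tree = obstacle_radii = None
    if crosslinkers:
        centers, radii = [], []
        for pl in crosslinkers:
            for c, r, _ in pl.world_beads():
                centers.append(c)
                radii.append(r)
        obstacle_tree = cKDTree(np.asarray(centers))
        obstacle_radii = np.asarray(radii)

    placements: List[Placement] = []
    chosen_by_filament: dict[int, set[int]] = {f: set() for f in outer}
    skipped: List[tuple[int, int]] = []

    def admissible(f: int, k: int) -> Optional[Placement]:
        cand = _motor_candidate(bundle, motor_spec, f, k)
        if cand.extra["radial_extension"] < min_radial_extension:
            return None
        if not _clash_free(
            bundle, cand, f, obstacle_tree, obstacle_radii, overlap_factor
        ):
            return None
        return cand

    for f in outer:
        phi = float(
            np.degrees(
                np.arctan2(bundle.lattice.points[f][1], bundle.lattice.points[f][0])
            )
            % 360.0
        )
        for r in range(bundle.n_repeats):
            window = range(r * u, (r + 1) * u)
            cands = []
            for k in window:
                c = admissible(f, k)
                if c is not None:
                    dev = circular_distance(bundle.monomer_azimuth(k), phi)
                    c.repeat_index = r
                    c.extra["facing_deviation"] = dev
                    cands.append(c)
            cands.sort(key=lambda c: (-c.extra["radial_extension"], c.domains[0].monomer))
            if not cands:
                skipped.append((f, r))
                logger.warning(
                    "no clash-free motor site on filament %d repeat %d", f, r
                )
                continue
            for c in cands[:2]:
                placements.append(c)
                chosen_by_filament[f].add(c.domains[0].monomer)

    # index step between adjacent outer filaments (one monomer along the
    # long-pitch helix) and the axial span of one 360° tour
    dphi = 360.0 / n_outer
    dk = min(
        range(1, u + 1), key=lambda k: circular_distance(k * sym.twist, dphi)
    )
    turn_monomers = dk * n_outer
    seam = outer[0]
    n_turns = bundle.monomers_per_filament // turn_monomers
    for t in range(n_turns):
        window = range(t * turn_monomers, (t + 1) * turn_monomers)
        best = None
        for k in window:
            if k in chosen_by_filament[seam]:
                continue
            c = admissible(seam, k)
            if c is None:
                continue
            key = (-c.extra["radial_extension"], k)
            if best is None or key < best[0]:
                best = (key, c)
        if best is None:
            logger.warning("no admissible third motor in turn %d", t)
            continue
        c = best[1]
        c.repeat_index = c.domains[0].monomer // u
        c.extra["turn_index"] = t
        placements.append(c)
        chosen_by_filament[seam].add(c.domains[0].monomer)

    placements.sort(key=lambda p: (p.domains[0].filament, p.domains[0].monomer))
    return MotorPlacementSet(
        placements=placements,
        skipped=skipped,
        turn_monomers=turn_monomers,
        n_outer=n_outer,
    )


def attach_light_chains(
    motor_placement: Placement, light_chain_spec: ComponentSpec
) -> List[Placement]:
    """One light chain per IQ frame along the motor's neck."""
    out = []
    for k, frame in enumerate(motor_placement.light_chain_frames()):
        dom = light_chain_spec.domains[0]
        out.append(
            Placement(
                component=light_chain_spec,
                domains=[
                    DomainPlacement(
                        dom,
                        motor_placement.domains[0].filament,
                        motor_placement.domains[0].monomer,
                        frame,
                    )
                ],
                parent=motor_placement,
                extra={"iq_index": k},
            )
        )
    return out


def barber_pole_parameters(
    motor_placements: Iterable[Placement],
    bundle: Bundle,
    min_cluster_fraction: float = 0.1,
) -> tuple[int, float, str]:
    """Fit the helical barber-pole pattern of motor anchors.

    Returns ``(n_strands, pitch_Å, handedness)``.

    The motor stripes are helical only locally — one full 360° tour of
    the outer ring falls one azimuthal grid step short of closing, so
    no single coherent helix threads all motors.  The pitch is
    therefore estimated from the local stripe slope: for every motor,
    the axial offset to the nearest motor on the azimuthally adjacent
    outer filament (the one-monomer-step-per-filament property of the
    axially registered lattice), whose median gives Å of rise per
    degree of azimuth.  Strands are the phase classes of the anchors
    modulo one symmetry repeat along z; clusters holding under
    ``min_cluster_fraction`` of the anchors (e.g. the seam motors) are
    not counted as strands.
    """
    pts = bundle.lattice.points
    anchors = []
    for p in motor_placements:
        f = p.domains[0].filament
        phi = float(np.degrees(np.arctan2(pts[f][1], pts[f][0])) % 360.0)
        anchors.append((phi, float(p.domains[0].transform.translation[2])))
    if len(anchors) < 6:
        raise InsufficientDataError(
            f"barber-pole fit needs several motors, got {len(anchors)}"
        )
    az = np.array([a for a, _ in anchors])
    z = np.array([b for _, b in anchors])
    if np.ptp(z) <= 0:
        raise InsufficientDataError("motors span no axial range")

    # group anchors by filament azimuth
    groups: dict[float, list[float]] = {}
    for a, zz in zip(np.round(az, 6), z):
        groups.setdefault(float(a), []).append(float(zz))
    phis = sorted(groups)
    if len(phis) < 2:
        raise InsufficientDataError("motors on fewer than two azimuths")
    # stripe slope: per adjacent filament pair, the axial shift that best
    # maps one motor set onto the next (set correlation, not per-motor
    # nearest neighbours, which would conflate the strands)
    rise = bundle.symmetry.rise
    u = bundle.symmetry.units_per_repeat or 13
    rates = []
    for idx, phi in enumerate(phis):
        nxt = phis[(idx + 1) % len(phis)]
        dphi = (nxt - phi) % 360.0
        if dphi == 0:
            continue
        z_here = np.array(groups[phi])
        z_next = np.array(groups[nxt])
        best = None
        for k in range(-u, u + 1):
            delta = k * rise
            hits = int(
                (np.abs(z_next[None, :] - (z_here[:, None] + delta)) < 0.5 * rise)
                .any(axis=1)
                .sum()
            )
            key = (-hits, abs(k), -np.sign(k))
            if best is None or key < best[0]:
                best = (key, delta)
        rates.append(best[1] / dphi)
    rate = float(np.median(rates))  # Å of axial rise per degree of azimuth
    if rate == 0:
        raise InsufficientDataError("motor stripes have no axial slope")
    pitch = abs(rate) * 360.0
    handedness = "right" if rate > 0 else "left"

    period = bundle.symmetry.units_per_repeat * rise
    phase = (z - rate * az) % period
    ph = np.sort(phase)
    # circular 1-D clustering: split at gaps larger than one rise
    breaks = np.nonzero(np.diff(ph) > rise)[0]
    clusters = [len(c) for c in np.split(ph, breaks + 1)]
    if len(clusters) > 1 and (ph[0] + period) - ph[-1] <= rise:
        clusters[0] += clusters.pop()
    n = sum(1 for c in clusters if c >= min_cluster_fraction * len(ph))
    return max(n, 1), float(pitch), handedness


# ---------------------------------------------------------------------------
# steric validation

@dataclass(frozen=True)
class Clash:
    placement_a: int
    placement_b: int
    bead_a: str
    bead_b: str
    distance: float


def detect_clashes(
    placements: Sequence[Placement], overlap_factor: float = 0.9
) -> List[Clash]:
    """All overlapping bead pairs between distinct, non-bonded components.

    Two beads clash when their centre distance is below
    ``overlap_factor × (r₁ + r₂)`` (soft core: coarse beads
    overestimate molecular envelopes).  Pairs within one placement, or
    between a placement and its bonded parent (a light chain on its
    own motor), are skipped.  kd-tree accelerated; the result is
    sorted and independent of bead insertion order.
    """
    centers, radii, owner, labels = [], [], [], []
    for idx, p in enumerate(placements):
        for c, r, lab in p.world_beads():
            centers.append(c)
            radii.append(r)
            owner.append(idx)
            labels.append(lab)
    if not centers:
        return []
    centers = np.asarray(centers)
    radii = np.asarray(radii)
    tree = cKDTree(centers)
    rmax = float(radii.max())
    clashes = []
    for a, b in tree.query_pairs(overlap_factor * 2 * rmax):
        ia, ib = owner[a], owner[b]
        if ia == ib:
            continue
        pa, pb = placements[ia], placements[ib]
        if pa.parent is pb or pb.parent is pa:
            continue
        d = float(np.linalg.norm(centers[a] - centers[b]))
        if d < overlap_factor * (radii[a] + radii[b]):
            i, j = sorted((ia, ib))
            la, lb = (labels[a], labels[b]) if ia <= ib else (labels[b], labels[a])
            clashes.append(Clash(i, j, la, lb, d))
    clashes.sort(key=lambda c: (c.placement_a, c.placement_b, c.bead_a, c.bead_b))
    return clashes
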