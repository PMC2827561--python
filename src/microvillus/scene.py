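"""In-situ brush-border scene: membrane, microvillus array, terminal web.

Scene-level geometry uses nm (the scale the tissue is measured at);
the underlying bundle model stays in Å and is converted on export.
Microvilli are ~1000 nm long, 50 nm in radius, wrapped in a 5 nm
membrane, hexagonally packed at 115–120 nm centre-to-centre; in situ
the actin barbed ends point apically, so bundle copies are flipped to
barbed-up.  Between adjacent bundle bases, coarse spectrin tetramers
(65 nm antiparallel double helices) form the terminal web.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import trimesh

from .assembly import Bundle
from .components import FILAMENT_RADIUS
from .errors import GeometryError, ParameterError
from .lattice import bundle_width, hex_points

logger = logging.getLogger(__name__)

__all__ = [
    "SceneSpec",
    "Scene",
    "SpectrinPath",
    "membrane_surface",
    "microvillus_array",
    "terminal_web",
    "scene_coordinates_table",
]


@dataclass(frozen=True)
class SceneSpec:
    """Brush-border dimensions (nm)."""

    mv_length: float = 1000.0
    mv_radius: float = 50.0
    membrane_thickness: float = 5.0
    mv_spacing: float = 120.0
    n_microvilli: int = 7
    spectrin_length: float = 65.0
    spectrin_pitch: float = 13.0
    spectrin_radius: float = 3.0
    spectrin_per_pair: int = 2

    def __post_init__(self) -> None:
        for name in ("mv_length", "mv_radius", "mv_spacing", "spectrin_length",
                     "spectrin_pitch", "spectrin_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.membrane_thickness < 0:
            raise ParameterError("membrane_thickness must be >= 0")
        if self.mv_spacing <= 2.0 * self.mv_radius:
            raise GeometryError(
                f"microvilli of radius {self.mv_radius} nm overlap at "
                f"{self.mv_spacing} nm spacing"
            )
        if self.n_microvilli < 1:
            raise ParameterError("need at least one microvillus")


def _capped_cylinder_mesh(radius: float, length: float,
                          n_theta: int, n_z: int, n_phi: int) -> trimesh.Trimesh:
    """Open-bottomed cylinder (z in [0, length]) + hemispherical cap."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    verts: List[np.ndarray] = []
    # cylinder rings bottom -> top
    for z in np.linspace(0.0, length, n_z):
        verts.append(
            np.column_stack(
                [radius * np.cos(theta), radius * np.sin(theta), np.full(n_theta, z)]
            )
        )
    # cap rings (exclude the equator ring already present), then apex
    for phi in np.linspace(0.0, np.pi / 2, n_phi + 1)[1:-1]:
        r = radius * np.cos(phi)
        verts.append(
            np.column_stack(
                [r * np.cos(theta), r * np.sin(theta),
                 np.full(n_theta, length + radius * np.sin(phi))]
            )
        )
    vertices = np.vstack(verts + [np.array([[0.0, 0.0, length + radius]])])
    apex = len(vertices) - 1
    faces = []
    n_rings = n_z + (n_phi - 1)
    for k in range(n_rings - 1):
        a = k * n_theta
        b = (k + 1) * n_theta
        for t in range(n_theta):
            t2 = (t + 1) % n_theta
            faces.append([a + t, a + t2, b + t])
            faces.append([a + t2, b + t2, b + t])
    top = (n_rings - 1) * n_theta
    for t in range(n_theta):
        faces.append([top + t, top + (t + 1) % n_theta, apex])
    return trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)


def membrane_surface(
    spec: SceneSpec, n_theta: int = 64, n_z: int = 40, n_phi: int = 24
) -> dict:
    """Triangulated membrane of one microvillus.

    Returns ``{"outer": mesh, "inner": mesh | None}`` (inner leaflet
    offset inward by the membrane thickness; ``None`` for zero
    thickness).  Mesh area converges quadratically in resolution to
    the analytic cylinder + hemisphere area.
    """
    outer = _capped_cylinder_mesh(spec.mv_radius, spec.mv_length, n_theta, n_z, n_phi)
    inner = None
    if spec.membrane_thickness > 0:
        r_in = spec.mv_radius - spec.membrane_thickness
        if r_in <= 0:
            raise ParameterError("membrane thicker than the microvillus radius")
        inner = _capped_cylinder_mesh(r_in, spec.mv_length, n_theta, n_z, n_phi)
    return {"outer": outer, "inner": inner}


@dataclass
class Scene:
    """A field of microvilli plus (optionally) a terminal web."""

    spec: SceneSpec
    centers: np.ndarray  # (n, 2) microvillus centres, nm
    bundle: Bundle  # barbed-up template shared by all copies
    web: List["SpectrinPath"] = field(default_factory=list)

    @property
    def bundle_diameter_nm(self) -> float:
        return bundle_width(self.bundle.lattice, FILAMENT_RADIUS, 0.0) / 10.0

    def filament_axes_nm(self) -> np.ndarray:
        """(n_mv × n_filaments, 2) filament axis positions, nm."""
        lat = self.bundle.lattice.points / 10.0
        return (self.centers[:, None, :] + lat[None, :, :]).reshape(-1, 2)


def microvillus_array(spec: SceneSpec, bundle_template: Bundle) -> Scene:
    """Hexagonally arrange barbed-up bundle copies at the scene spacing."""
    diameter_nm = bundle_width(bundle_template.lattice, FILAMENT_RADIUS, 0.0) / 10.0
    if spec.mv_spacing < diameter_nm:
        raise GeometryError(
            f"bundle diameter {diameter_nm:.1f} nm exceeds microvillus "
            f"spacing {spec.mv_spacing} nm"
        )
    rings = 0
    while 3 * rings * rings + 3 * rings + 1 < spec.n_microvilli:
        rings += 1
    lat = hex_points(rings, spec.mv_spacing)
    centers = lat.points[: spec.n_microvilli].copy()
    bundle = Bundle(
        symmetry=bundle_template.symmetry,
        lattice=bundle_template.lattice,
        monomers_per_filament=bundle_template.monomers_per_filament,
        polarity="barbed-up",
    )
    return Scene(spec=spec, centers=centers, bundle=bundle)


@dataclass
class SpectrinPath:
    """Coarse spectrin tetramer linking two adjacent bundle bases."""

    pair: tuple  # (microvillus index a, microvillus index b)
    strands: List[np.ndarray]  # two (n, 3) point paths, nm
    end_to_end: float  # nm
    compressed: bool = False

    def contour_length(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.strands)
            / len(self.strands)
        )


def _double_helix(start: np.ndarray, end: np.ndarray, pitch: float,
                  radius: float, n_pts: int = 80) -> List[np.ndarray]:
    """Antiparallel double helix whose two strands join the endpoints."""
    axis = end - start
    length = float(np.linalg.norm(axis))
    u = axis / length
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    t = np.linspace(0.0, 1.0, n_pts)
    ang = 2 * np.pi * length * t / pitch
    taper = radius * np.sin(np.pi * t)  # strands meet at both junctions
    strands = []
    for phase in (0.0, np.pi):
        offs = taper[:, None] * (
            np.cos(ang + phase)[:, None] * e1 + np.sin(ang + phase)[:, None] * e2
        )
        strands.append(start + t[:, None] * axis + offs)
    # antiparallel: the second strand runs end -> start
    strands[1] = strands[1][::-1]
    return strands


def terminal_web(scene: Scene, z_nm: float = 0.0) -> List[SpectrinPath]:
    """Link every adjacent microvillus pair with coarse spectrin tetramers.

    ``spectrin_per_pair`` tetramers per adjacent pair are laid at
    descending z below ``z_nm`` (the bundle base).  Each tetramer is a
    double helix of end-to-end length ``spectrin_length``, centred in
    the inter-bundle gap; a gap below half that length logs a
    compressed-web warning.
    """
    if len(scene.centers) < 2:
        raise ParameterError("terminal web needs at least two microvilli")
    spec = scene.spec
    r_bundle = scene.bundle_diameter_nm / 2.0
    paths: List[SpectrinPath] = []
    n = len(scene.centers)
    for a in range(n):
        for b in range(a + 1, n):
            d = float(np.linalg.norm(scene.centers[b] - scene.centers[a]))
            if abs(d - spec.mv_spacing) > 0.01 * spec.mv_spacing:
                continue
            gap = d - 2.0 * r_bundle
            compressed = gap < 0.5 * spec.spectrin_length
            if compressed:
                logger.warning(
                    "inter-bundle gap %.1f nm < half the spectrin length; "
                    "web between %d and %d is compressed", gap, a, b
                )
            u = (scene.centers[b] - scene.centers[a]) / d
            mid = (scene.centers[a] + scene.centers[b]) / 2.0
            half = spec.spectrin_length / 2.0
            for m in range(spec.spectrin_per_pair):
                z = z_nm - 10.0 * m
                start = np.array([*(mid - half * u), z])
                end = np.array([*(mid + half * u), z])
                strands = _double_helix(
                    start, end, spec.spectrin_pitch, spec.spectrin_radius
                )
                paths.append(
                    SpectrinPath(
                        pair=(a, b),
                        strands=strands,
                        end_to_end=float(np.linalg.norm(end - start)),
                        compressed=compressed,
                    )
                )
    scene.web = paths
    return paths


def scene_coordinates_table(scene: Scene, path: Union[str, Path]) -> None:
    """Plain TSV of scene landmarks (microvillus centres, filament axes,
    spectrin strand points), columns: kind, index, x_nm, y_nm, z_nm."""
    rows = []
    for i, c in enumerate(scene.centers):
        rows.append(("microvillus_center", i, c[0], c[1], 0.0))
    lat = scene.bundle.lattice.points / 10.0
    for i, c in enumerate(scene.centers):
        for j, p in enumerate(lat):
            rows.append(("filament_axis", i * len(lat) + j, c[0] + p[0], c[1] + p[1], 0.0))
    for k, w in enumerate(scene.web):
        for s_idx, strand in enumerate(w.strands):
            for p in strand:
                rows.append((f"spectrin_{k}_strand{s_idx}", k, p[0], p[1], p[2]))
    with open(path, "w") as fh:
        fh.write("kind\tindex\tx_nm\ty_nm\tz_nm\n")
        for kind, idx, x, y, z in rows:
            fh.write(f"{kind}\t{idx}\t{x:.3f}\t{y:.3f}\t{z:.3f}\n")
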