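"""Helical symmetry operators and the hexagonal-mismatch analysis.

An actin filament is generated from one monomer by a screw operation:
a rise along z (27.57 Å for F-actin) and a twist about z (−166.154°)
per monomer.  When an integer number of monomers ``u`` completes an
integer number of full turns ``t`` of the short-pitch helix, the
filament has *u/t* symmetry; for F-actin this is 13/6 — thirteen
monomers per six turns, so monomer ``i`` and monomer ``i + 13`` are
rotationally equivalent.

Embedding a 13/6 helix in a hexagonal filament lattice is frustrated:
the azimuths at which monomers (and hence binding sites) point are
multiples of the twist, which do not coincide with the three hexagonal
bond axes (0°, 60°, 120°).  :func:`hexagonal_mismatch` quantifies the
angular accommodation a two-domain cross-linker must supply, and the
angular spacing between achievable cross-link axes, which bounds the
flexibility compatible with a *unique* cross-link site per repeat.

Angles are degrees throughout; lengths are Å; trigonometry is done in
radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateSymmetryError, ParameterError, UnsupportedSymmetryError

__all__ = [
    "RigidTransform",
    "HelicalSymmetry",
    "make_symmetry",
    "monomer_transform",
    "achievable_axes",
    "hexagonal_mismatch",
    "circular_distance",
    "ACTIN_RISE",
    "ACTIN_TWIST",
]

#: F-actin helical parameters (Holmes-model filament geometry).
ACTIN_RISE = 27.57  # Å per monomer
ACTIN_TWIST = -166.154  # degrees per monomer

_ORTHO_TOL = 1e-9


def circular_distance(a: float, b: float, period: float = 360.0) -> float:
    """Smallest angular distance between ``a`` and ``b`` on a circle."""
    d = abs(a - b) % period
    return min(d, period - d)


@dataclass
class RigidTransform:
    """Proper rigid-body transform: ``x -> rotation @ x + translation``.

    ``rotation`` must be a proper orthonormal 3×3 matrix (det = +1);
    ``translation`` is a 3-vector in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ParameterError("rotation must be a 3x3 matrix")
        if not np.all(np.isfinite(self.rotation)) or not np.all(
            np.isfinite(self.translation)
        ):
            raise ParameterError("transform entries must be finite")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8:
            raise ParameterError(f"rotation is not orthonormal (error {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ParameterError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_z(cls, angle_deg: float, dz: float = 0.0) -> "RigidTransform":
        """Screw motion: rotation about z by ``angle_deg``, translation dz."""
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return cls(rot, np.array([0.0, 0.0, dz]))

    @classmethod
    def about_x(cls, angle_deg: float) -> "RigidTransform":
        a = np.deg2rad(angle_deg)
        c, s = np.cos(a), np.sin(a)
        rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        return cls(rot, np.zeros(3))

    @classmethod
    def from_translation(cls, t: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``(self ∘ other)(x) = self(other(x))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector) of coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def is_close(self, other: "RigidTransform", tol: float = _ORTHO_TOL) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )


@dataclass(frozen=True)
class HelicalSymmetry:
    """Screw symmetry of a filament, with detected repeat closure.

    ``units_per_repeat``/``turns_per_repeat`` are populated when an
    integer number of monomers closes onto an integer number of turns
    within ``closure_tolerance`` (degrees of total residual rotation);
    otherwise both are ``None``.
    """

    rise: float
    twist: float
    units_per_repeat: Optional[int] = None
    turns_per_repeat: Optional[int] = None
    closure_tolerance: float = field(default=0.01)

    @property
    def closed(self) -> bool:
        return self.units_per_repeat is not None

    @property
    def repeat_length(self) -> Optional[float]:
        """Axial length of one repeat in Å, if closure was detected."""
        if not self.closed:
            return None
        return self.units_per_repeat * self.rise


def _normalize_twist(twist: float) -> float:
    """Map a twist angle to the interval (−180, 180]."""
    t = -((-twist + 180.0) % 360.0 - 180.0)
    return 180.0 if t == -180.0 else t


def make_symmetry(
    rise: float,
    twist: float,
    closure_tolerance: float = 0.01,
    max_units: int = 1000,
) -> HelicalSymmetry:
    """Build a :class:`HelicalSymmetry`, detecting u/t repeat closure.

    Closure is the smallest ``u <= max_units`` for which ``u × twist``
    lies within ``closure_tolerance`` degrees of a multiple of 360°.
    F-actin's printed twist of −166.154°/monomer accumulates a residual
    of 0.002° over 13 monomers, so the default tolerance (0.01°) reads
    it as 13/6; a genuinely incommensurate twist (e.g. the −166.40°
    variant, 0.25°/monomer away from 13/6) is left open.
    """
    if not np.isfinite(rise) or rise <= 0:
        raise ParameterError(f"rise must be positive, got {rise}")
    if max_units < 1:
        raise ParameterError("max_units must be >= 1")
    t = _normalize_twist(float(twist))
    if abs(t) < 1e-12:
        raise DegenerateSymmetryError("zero twist: filament is not helical")

    units = turns = None
    for u in range(1, max_units + 1):
        total = u * t
        residual = abs((total + 180.0) % 360.0 - 180.0)
        n_turns = abs(int(round(total / 360.0)))
        if residual <= closure_tolerance and n_turns >= 1:
            units, turns = u, n_turns
            break
    return HelicalSymmetry(
        rise=float(rise),
        twist=t,
        units_per_repeat=units,
        turns_per_repeat=turns,
        closure_tolerance=closure_tolerance,
    )


def monomer_transform(sym: HelicalSymmetry, i: int) -> RigidTransform:
    """Screw operation carrying monomer 0 to monomer ``i`` (any integer)."""
    return RigidTransform.about_z(i * sym.twist, i * sym.rise)


def achievable_axes(sym: HelicalSymmetry, dedup_tol: float = 1e-6) -> np.ndarray:
    """Undirected cross-link axis orientations achievable within one repeat.

    Monomer ``k`` points at azimuth ``k × twist``; an undirected bond
    axis identifies θ with θ + 180°, so the achievable axes are
    ``{k × twist mod 180° : k = 0..u−1}``, deduplicated and sorted.
    """
    if not sym.closed:
        raise UnsupportedSymmetryError(
            "no repeat closure detected; achievable axes undefined"
        )
    u = sym.units_per_repeat
    vals = np.sort((np.arange(u) * sym.twist) % 180.0)
    keep = [vals[0]]
    for v in vals[1:]:
        if v - keep[-1] > dedup_tol:
            keep.append(v)
    # wrap-around duplicate (e.g. 179.999999 ~ 0)
    if len(keep) > 1 and (keep[0] + 180.0) - keep[-1] <= dedup_tol:
        keep.pop()
    return np.asarray(keep)


def _facing_deviation(theta: float, azimuths: np.ndarray) -> float:
    """Distance from a *directed* bond direction to the nearest monomer azimuth."""
    d = np.abs((azimuths - theta + 180.0) % 360.0 - 180.0)
    return float(d.min())


def hexagonal_mismatch(sym: HelicalSymmetry) -> tuple[float, float]:
    """Angular frustration of a closed helix in a hexagonal lattice.

    Returns ``(max_deviation, uniqueness_spacing)`` in degrees.

    A cross-link along a hexagonal bond axis θ needs a monomer facing θ
    on one filament and a monomer facing θ + 180° on the other (all
    filaments are unipolar and in axial register, so their monomer
    azimuths rotate in phase).  The total angular misfit for the best
    monomer pair is split equally between the two binding domains, so

        deviation(θ) = (dist(θ, A) + dist(θ + 180°, A)) / 2,

    where A is the set of achievable monomer azimuths mod 360°, and
    ``max_deviation`` is the worst case over θ ∈ {0°, 60°, 120°}.  For
    13/6 actin the misfit is the same 13.85° for every bond direction,
    giving ±6.92° per domain (the "±7°" flexibility requirement); for
    an ideal hexagonal 6/1 helix it is exactly 0.

    ``uniqueness_spacing`` is the gap between adjacent achievable
    undirected axes (180°/13 ≈ 13.85° for 13/6): a cross-linker whose
    flexibility exceeded ±spacing could also bind in the reciprocal,
    filament-swapped orientation, destroying the unique site per repeat.
    """
    if not sym.closed:
        raise UnsupportedSymmetryError("hexagonal mismatch requires repeat closure")
    u = sym.units_per_repeat
    azimuths = (np.arange(u) * sym.twist) % 360.0
    max_dev = max(
        0.5 * (_facing_deviation(th, azimuths) + _facing_deviation(th + 180.0, azimuths))
        for th in (0.0, 60.0, 120.0)
    )
    axes = achievable_axes(sym)
    if len(axes) == 1:
        spacing = 180.0
    else:
        gaps = np.diff(axes)
        wrap = axes[0] + 180.0 - axes[-1]
        spacing = float(min(gaps.min(), wrap))
    return float(max_dev), spacing
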