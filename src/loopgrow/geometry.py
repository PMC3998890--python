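"""Internal-coordinate geometry: dihedral-driven atom placement and measurement,
the circle/sphere constructions used by distance-guided growth, and fixed-frame
backbone RMSD.

All positions are plain ``(3,)`` float64 numpy arrays in Å. Angles cross module
boundaries in degrees; radians are used internally. Dihedrals live in
``[-180, 180)`` and follow the IUPAC sign convention (right-handed about the
b→c axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "BondGeometry",
    "Circle3",
    "Frame",
    "place_atom",
    "place_atoms",
    "measure_dihedral",
    "measure_angle",
    "placement_circle",
    "intersect_circle_sphere",
    "backbone_rmsd",
    "wrap_degrees",
]

BACKBONE_ATOMS_4 = ("N", "CA", "C", "O")
BACKBONE_ATOMS_3 = ("N", "CA", "C")

_AREA_EPS = 1e-9



def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array([
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    ]) if a.ndim == 1 else np.stack([
        a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
        a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
        a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0],
    ], axis=-1)

class GeometryError(ValueError):
    """Degenerate geometric construction (collinear frame, impossible angle...)."""


@dataclass(frozen=True)
class BondGeometry:
    """Bond length (Å) and preceding bond angle (degrees) for placing one atom.

    ``bond_angle`` is the angle at the frame's last atom between the previous
    bond and the new bond.
    """

    bond_length: float
    bond_angle: float

    def __post_init__(self) -> None:
        if not (0.8 <= self.bond_length <= 2.6):
            raise ValueError(f"bond_length {self.bond_length} outside sane range")
        if not (0.0 < self.bond_angle < 180.0):
            raise ValueError(f"bond_angle {self.bond_angle} must be in (0, 180)")


@dataclass(frozen=True)
class Circle3:
    """A circle in 3-space: center, radius and unit normal."""

    center: np.ndarray
    radius: float
    normal: np.ndarray

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GeometryError("circle radius must be positive")
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            raise GeometryError("circle normal must be a unit vector")

    def point_at(self, theta: float | np.ndarray) -> np.ndarray:
        """Point(s) on the circle at angle ``theta`` (radians) from a fixed
        in-plane axis."""
        u, v = _circle_basis(self.normal)
        theta = np.asarray(theta, dtype=float)
        return (
            self.center
            + self.radius * np.cos(theta)[..., None] * u
            + self.radius * np.sin(theta)[..., None] * v
        )


@dataclass(frozen=True)
class Frame:
    """Three previously placed atoms (a, b, c) defining the placement frame for
    the next atom bonded to ``c``."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        area2 = np.linalg.norm(_cross3(self.b - self.a, self.c - self.a))
        if area2 / 2.0 <= _AREA_EPS:
            raise GeometryError("frame atoms are (nearly) collinear")


def wrap_degrees(angle):
    """Map angle(s) in degrees onto [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector")
    return v / n


def _circle_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(_cross3(normal, ref))
    v = _cross3(normal, u)
    return u, v


def place_atom(frame: Frame, geom: BondGeometry, dihedral: float) -> np.ndarray:
    """Place the atom bonded to ``frame.c`` by NeRF-style construction.

    The new atom sits at ``geom.bond_length`` from c, forms ``geom.bond_angle``
    with the b→c bond, and has dihedral ``dihedral`` (degrees) about b→c
    measured from a.
    """
    return place_atoms(frame, geom, np.asarray([dihedral], dtype=float))[0]


def place_atoms(frame: Frame, geom: BondGeometry, dihedrals: np.ndarray) -> np.ndarray:
    """Vectorized :func:`place_atom` over an array of dihedrals (degrees)."""
    bc = _unit(frame.c - frame.b)
    n = _cross3(frame.b - frame.a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise GeometryError("degenerate frame: a, b, c collinear")
    n = n / nn
    m = _cross3(n, bc)  # bc, m, n: right-handed orthonormal triad

    theta = np.deg2rad(geom.bond_angle)
    tau = np.deg2rad(np.asarray(dihedrals, dtype=float))
    r = geom.bond_length
    # local displacement: along -bc then rotated by (pi - theta), torsion tau
    d = (
        -r * np.cos(theta) * bc
        + (r * np.sin(theta) * np.cos(tau))[:, None] * m
        + (r * np.sin(theta) * np.sin(tau))[:, None] * n
    )
    return frame.c + d


def measure_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = _unit(a - b)
    v = _unit(c - b)
    return float(np.rad2deg(np.arccos(np.clip(u @ v, -1.0, 1.0))))


def measure_dihedral(a, b, c, d) -> float:
    """Dihedral angle of the four points in degrees, in [-180, 180).

    Sign is right-handed about the b→c axis (IUPAC). Raises
    :class:`GeometryError` when a,b,c or b,c,d are collinear.
    """
    b0 = np.asarray(b) - np.asarray(a)
    b1 = np.asarray(c) - np.asarray(b)
    b2 = np.asarray(d) - np.asarray(c)
    n1 = _cross3(b0, b1)
    n2 = _cross3(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear points: dihedral undefined")
    b1u = b1 / np.linalg.norm(b1)
    x = n1 @ n2
    y = _cross3(n1, n2) @ b1u
    ang = np.rad2deg(np.arctan2(y, x))
    return float(wrap_degrees(ang))


def placement_circle(prev2: np.ndarray, prev1: np.ndarray, geom: BondGeometry) -> Circle3:
    """Circle of all positions at ``geom.bond_length`` from ``prev1`` forming
    ``geom.bond_angle`` with the prev2→prev1 bond.

    This is the locus traced by the next backbone atom as its dihedral spins.
    """
    axis = _unit(prev1 - prev2)
    theta = np.deg2rad(geom.bond_angle)
    if not (1e-9 < theta < np.pi - 1e-9):
        raise GeometryError("degenerate circle: bond angle of 0 or 180 degrees")
    # new bond makes angle (pi - theta) with +axis direction
    h = -geom.bond_length * np.cos(theta)  # signed offset along axis
    radius = geom.bond_length * np.sin(theta)
    center = prev1 + h * axis
    return Circle3(center=center, radius=radius, normal=axis)


def intersect_circle_sphere(
    circle: Circle3, anchor: np.ndarray, dist: float, *, tol: float = 1e-9
) -> list[np.ndarray]:
    """Intersect a circle with the sphere of radius ``dist`` about ``anchor``.

    Returns 0, 1 (tangency) or 2 points, each satisfying both constraints to
    within ``tol``. An anchor on the circle's axis at exactly the right
    distance has a continuum of solutions and raises :class:`GeometryError`.
    """
    if dist <= 0:
        raise ValueError("dist must be positive")
    w = anchor - circle.center
    h = w @ circle.normal  # axial offset of anchor from circle plane
    w_in = w - h * circle.normal  # in-plane component
    rho = np.linalg.norm(w_in)
    r = circle.radius
    if rho < 1e-9:
        # axis-symmetric: either no point or the full circle works
        d_all = np.hypot(r, h)
        if abs(d_all - dist) <= tol:
            raise GeometryError("degenerate: anchor on circle axis, infinite solutions")
        return []
    # point on circle at angle t from w_in direction: |P-anchor|^2 =
    # r^2 + rho^2 + h^2 - 2 r rho cos t
    cos_t = (r * r + rho * rho + h * h - dist * dist) / (2.0 * r * rho)
    if abs(cos_t) > 1.0 + 1e-12:
        return []
    cos_t = float(np.clip(cos_t, -1.0, 1.0))
    t = np.arccos(cos_t)
    e1 = w_in / rho
    e2 = _cross3(circle.normal, e1)
    p_plus = circle.center + r * (np.cos(t) * e1 + np.sin(t) * e2)
    if t < 1e-9 or abs(t - np.pi) < 1e-9:
        return [p_plus]  # tangency
    p_minus = circle.center + r * (np.cos(t) * e1 - np.sin(t) * e2)
    return [p_plus, p_minus]


def backbone_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> float:
    """Fixed-frame RMSD between two matched coordinate arrays of shape (n, 3).

    No superposition is performed: the protein body is held fixed and the two
    conformations are compared in the same frame.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate arrays must have matching (n, 3) shapes, got {a.shape} vs {b.shape}")
    if a.shape[0] == 0:
        raise ValueError("empty coordinate arrays")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
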