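"""Analytic tripeptide loop closure.

Reconnects a grown chain to the fixed C-terminal anchor by solving for the
backbone of the last two loop residues plus the anchor residue's rebuilt N.
The three pivot Cα atoms are: Cα of the penultimate loop residue (grown and
fixed), Cα of the last loop residue (solved), and the anchor Cα (fixed).
Between pivots the peptide units are rigid bodies (fixed bond lengths, bond
angles and ω), so the closure reduces to three unknowns — the position of the
middle Cα on its two-sphere intersection circle (angle α) and the two unit
rotations τ1, τ2 about the virtual Cα–Cα axes — bound by the three N–Cα–C
bond-angle constraints at the pivots.

The solver scans α, solves τ1 and τ2 in closed form per branch (each angle
constraint is A·cosτ + B·sinτ = D), and polishes sign changes of the middle
bond-angle residual with Brent's method. This is a numerically robust
equivalent of the classic 16-degree-polynomial formulation: it returns the
same discrete solution set (at most 16), each verified against the residual
tolerances by forward rebuilding.

Small Gaussian jitter on bond lengths, bond angles and ω raises the closure
success rate when the anchors sit at the edge of reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from . import chemistry
from .geometry import (
    Frame,
    GeometryError,
    measure_angle,
    measure_dihedral,
    place_atom,
    wrap_degrees,
)

RESIDUAL_BOND_TOL = 1e-4  # Å
RESIDUAL_ANGLE_TOL = 1e-3  # degrees
MAX_SOLUTIONS = 16
N_SCAN = 512



def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product without numpy's generic-axis overhead (hot path)."""
    if a.ndim == 1 and b.ndim == 1:
        return np.array([
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ])
    return np.stack([
        a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
        a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
        a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0],
    ], axis=-1)

class ClosureFailure(RuntimeError):
    """No closure solution found within the attempt budget."""


@dataclass(frozen=True)
class JitterSpec:
    sigma_bond: float = 0.01  # Å
    sigma_angle: float = 1.0  # degrees
    sigma_omega: float = 2.0  # degrees
    max_attempts: int = 20


@dataclass(frozen=True)
class UnitGeometry:
    """Internal geometry of one rigid peptide unit Cα_i → Cα_{i+1}."""

    b_ca_c: float
    ang_ca_c_n: float
    b_c_n: float
    omega: float
    ang_c_n_ca: float
    b_n_ca: float


@dataclass
class ClosureProblem:
    """Fixed frames, residue types and target geometry for one closure.

    ``n_frame``: last three grown backbone atoms (C of residue e-2, N and Cα
    of residue e-1). ``c_frame``: the first three fixed anchor atoms (N, Cα,
    C of the residue after the loop). ``residue_types``: types of residue
    e-1, residue e, and the anchor residue.
    """

    n_frame: tuple[np.ndarray, np.ndarray, np.ndarray]
    c_frame: tuple[np.ndarray, np.ndarray, np.ndarray]
    residue_types: tuple[str, str, str]
    unit1: UnitGeometry = None  # type: ignore[assignment]
    unit2: UnitGeometry = None  # type: ignore[assignment]
    theta1: float = None  # N-CA-C at the first pivot  # type: ignore[assignment]
    theta2: float = None  # N-CA-C at the middle pivot  # type: ignore[assignment]
    theta3: float = None  # (rebuilt N)-CA-C at the anchor  # type: ignore[assignment]
    jitter: JitterSpec = field(default_factory=JitterSpec)

    def __post_init__(self) -> None:
        geo = chemistry.backbone_geometry()
        r1, r2, r3 = self.residue_types
        b = geo.bonds
        if self.unit1 is None:
            self.unit1 = UnitGeometry(
                b["CA-C"], geo.angles["CA-C-N"], b["C-N"], geo.omega_trans,
                geo.angle_c_n_ca(r2), b["N-CA"],
            )
        if self.unit2 is None:
            self.unit2 = UnitGeometry(
                b["CA-C"], geo.angles["CA-C-N"], b["C-N"], geo.omega_trans,
                geo.angle_c_n_ca(r3), b["N-CA"],
            )
        if self.theta1 is None:
            self.theta1 = geo.angle_n_ca_c(r1)
        if self.theta2 is None:
            self.theta2 = geo.angle_n_ca_c(r2)
        if self.theta3 is None:
            # junction angle target measured from the fixed anchor frame
            self.theta3 = measure_angle(*self.c_frame)
        for p in (*self.n_frame, *self.c_frame):
            if not np.all(np.isfinite(p)):
                raise GeometryError("non-finite frame coordinates")
        Frame(*self.n_frame)
        Frame(*self.c_frame)


@dataclass
class ClosureSolution:
    """One exact reconnection: six backbone dihedrals, the rebuilt atom
    coordinates, and the junction residuals from forward verification."""

    dihedrals: dict[str, float]
    atoms: dict[str, np.ndarray]  # C1 O1 N2 CA2 C2 O2 N3
    residual_bond: float
    residual_angle: float

    @property
    def accepted(self) -> bool:
        return (
            self.residual_bond <= RESIDUAL_BOND_TOL
            and self.residual_angle <= RESIDUAL_ANGLE_TOL
        )


def _unit_local(u: UnitGeometry) -> dict[str, np.ndarray]:
    """Atom coordinates of one rigid unit in its local frame (Cα_i at origin)."""
    ca_i = np.array([0.0, 0.0, 0.0])
    c = np.array([u.b_ca_c, 0.0, 0.0])
    # N in the z=0 plane
    ang = np.deg2rad(u.ang_ca_c_n)
    n = c + u.b_c_n * np.array([-np.cos(ang), np.sin(ang), 0.0])
    ca_j = place_atom(
        Frame(ca_i, c, n),
        chemistry.BondGeometry(u.b_n_ca, u.ang_c_n_ca),
        u.omega,
    )
    return {"CA_i": ca_i, "C": c, "N": n, "CA_j": ca_j}


def _axis_decomposition(local: dict[str, np.ndarray]) -> dict:
    """Axial offset, radius and phase of C and N about the Cα_i→Cα_j axis."""
    axis = local["CA_j"] - local["CA_i"]
    d = float(np.linalg.norm(axis))
    u = axis / d
    # deterministic perpendicular basis in the local frame
    ref = np.array([0.0, 0.0, 1.0])
    e1 = _cross3(ref, u)
    if np.linalg.norm(e1) < 1e-8:
        e1 = _cross3(np.array([0.0, 1.0, 0.0]), u)
    e1 /= np.linalg.norm(e1)
    e2 = _cross3(u, e1)
    out = {"d": d}
    for name in ("C", "N"):
        v = local[name] - local["CA_i"]
        x = float(v @ u)
        perp = v - x * u
        r = float(np.linalg.norm(perp))
        phase = float(np.arctan2(perp @ e2, perp @ e1))
        out[name] = (x, r, phase)
    return out


def _place_unit(
    start: np.ndarray, endp: np.ndarray, decomp: dict, tau: float
) -> dict[str, np.ndarray]:
    """Global positions of the unit's C and N for rotation phase ``tau``."""
    axis = endp - start
    u = axis / np.linalg.norm(axis)
    e1, e2 = _perp_basis(u)
    out = {}
    for name in ("C", "N"):
        x, r, phase = decomp[name]
        a = tau + phase
        out[name] = start + x * u + r * (np.cos(a) * e1 + np.sin(a) * e2)
    return out


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _cross3(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = _cross3(u, e1)
    return e1, e2


def _tau_roots(
    start: np.ndarray,
    endp: np.ndarray,
    decomp: dict,
    atom: str,
    other: np.ndarray,
    pivot: np.ndarray,
    theta: float,
) -> list[float]:
    """Solve A·cosτ + B·sinτ = D for the unit rotation that makes
    angle(other, pivot, unit_atom) equal ``theta``. Returns 0-2 roots."""
    axis = endp - start
    u = axis / np.linalg.norm(axis)
    e1, e2 = _perp_basis(u)
    x, r, phase = decomp[atom]
    base = start + x * u - pivot  # axial part of (atom - pivot); ⟂ to e1, e2
    v = other - pivot
    nv = np.linalg.norm(v)
    # rigid |atom - pivot|: base is along the axis, the rest is the radius
    la = float(np.sqrt(np.linalg.norm(base) ** 2 + r**2))
    target = np.cos(np.deg2rad(theta)) * nv * la
    # (base + r cos a e1 + r sin a e2) · v = target, a = tau + phase
    A = r * (e1 @ v)
    B = r * (e2 @ v)
    D = target - base @ v
    rad = A * A + B * B - D * D
    if rad < 0:
        if rad > -1e-12 * max(A * A + B * B, 1.0):
            rad = 0.0
        else:
            return []
    phi = np.arctan2(B, A)
    delta = np.arctan2(np.sqrt(rad), D)
    return [float(phi + delta - phase), float(phi - delta - phase)]


def _vec_perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise version of :func:`_perp_basis` for (S, 3) unit vectors."""
    ref = np.where(
        (np.abs(u @ np.array([1.0, 0.0, 0.0])) > 0.9)[:, None],
        np.array([0.0, 1.0, 0.0]),
        np.array([1.0, 0.0, 0.0]),
    )
    e1 = _cross3(u, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = _cross3(u, e1)
    return e1, e2


def _vec_tau_roots(start, endp, decomp, atom, other, pivot, theta):
    """Vectorized :func:`_tau_roots`: returns (valid, tau_a, tau_b) arrays."""
    axis = endp - start
    d = np.linalg.norm(axis, axis=1, keepdims=True)
    u = axis / d
    e1, e2 = _vec_perp_basis(u)
    x, r, phase = decomp[atom]
    base = start + x * u - pivot
    v = other - pivot
    nv = np.linalg.norm(v)
    la = np.sqrt(np.einsum("ij,ij->i", base, base) + r * r)
    target = np.cos(np.deg2rad(theta)) * nv * la
    A = r * (e1 @ v)
    B = r * (e2 @ v)
    D = target - base @ v
    rad = A * A + B * B - D * D
    valid = rad >= -1e-12 * np.maximum(A * A + B * B, 1.0)
    rad = np.maximum(rad, 0.0)
    phi = np.arctan2(B, A)
    delta = np.arctan2(np.sqrt(rad), D)
    return valid, phi + delta - phase, phi - delta - phase


def _vec_place(start, endp, decomp, atom, tau):
    axis = endp - start
    d = np.linalg.norm(axis, axis=1, keepdims=True)
    u = axis / d
    e1, e2 = _vec_perp_basis(u)
    x, r, phase = decomp[atom]
    a = tau + phase
    return start + x * u + r * (np.cos(a)[:, None] * e1 + np.sin(a)[:, None] * e2)


def solve_closure(problem: ClosureProblem, n_scan: int = N_SCAN) -> list[ClosureSolution]:
    """All discrete closure solutions (possibly empty, at most 16)."""
    c0, n1, ca1 = (np.asarray(p, dtype=float) for p in problem.n_frame)
    n_a, ca3, c3 = (np.asarray(p, dtype=float) for p in problem.c_frame)

    loc1 = _unit_local(problem.unit1)
    loc2 = _unit_local(problem.unit2)
    dec1 = _axis_decomposition(loc1)
    dec2 = _axis_decomposition(loc2)
    d1, d2 = dec1["d"], dec2["d"]

    base = ca3 - ca1
    db = float(np.linalg.norm(base))
    if db >= d1 + d2 or db <= abs(d1 - d2) or db < 1e-9:
        return []
    # circle of the middle pivot
    ub = base / db
    cos_g = (d1 * d1 + db * db - d2 * d2) / (2 * d1 * db)
    if abs(cos_g) > 1.0:
        return []
    proj = d1 * cos_g
    rad = d1 * np.sqrt(max(0.0, 1.0 - cos_g * cos_g))
    if rad < 1e-9:
        return []
    center = ca1 + proj * ub
    e1c, e2c = _perp_basis(ub)

    def ca2_at(alpha: float) -> np.ndarray:
        return center + rad * (np.cos(alpha) * e1c + np.sin(alpha) * e2c)

    def branch_F(alpha: float, s1: int, s2: int) -> float | None:
        ca2 = ca2_at(alpha)
        t1 = _tau_roots(ca1, ca2, dec1, "C", n1, ca1, problem.theta1)
        t2 = _tau_roots(ca2, ca3, dec2, "N", c3, ca3, problem.theta3)
        if not t1 or not t2:
            return None
        tau1 = t1[s1]
        tau2 = t2[s2]
        u1 = _place_unit(ca1, ca2, dec1, tau1)
        u2 = _place_unit(ca2, ca3, dec2, tau2)
        try:
            return measure_angle(u1["N"], ca2, u2["C"]) - problem.theta2
        except GeometryError:
            return None

    solutions: list[ClosureSolution] = []
    alphas = np.linspace(0.0, 2.0 * np.pi, n_scan, endpoint=False)

    def eval_grid(a: np.ndarray):
        """Vectorized F over an alpha array for all four tau branches, plus
        the per-unit validity masks."""
        ca2_all = center + rad * np.cos(a)[:, None] * e1c + rad * np.sin(a)[:, None] * e2c
        ca1_b = np.broadcast_to(ca1, ca2_all.shape)
        ca3_b = np.broadcast_to(ca3, ca2_all.shape)
        v1_ok, t1a, t1b = _vec_tau_roots(ca1_b, ca2_all, dec1, "C", n1, ca1, problem.theta1)
        v2_ok, t2a, t2b = _vec_tau_roots(ca2_all, ca3_b, dec2, "N", c3, ca3, problem.theta3)
        out: dict[tuple[int, int], np.ndarray] = {}
        for s1, t1 in ((0, t1a), (1, t1b)):
            n2 = _vec_place(ca1_b, ca2_all, dec1, "N", t1)
            for s2, t2 in ((0, t2a), (1, t2b)):
                c2 = _vec_place(ca2_all, ca3_b, dec2, "C", t2)
                va = n2 - ca2_all
                vb = c2 - ca2_all
                cosang = np.einsum("ij,ij->i", va, vb) / (
                    np.linalg.norm(va, axis=1) * np.linalg.norm(vb, axis=1)
                )
                f = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))) - problem.theta2
                f[~(v1_ok & v2_ok)] = np.nan
                out[(s1, s2)] = f
        return out, v1_ok, v2_ok

    def disc(alpha: float, unit: int) -> float:
        """Scalar tau-root discriminant of one unit (zero at the validity
        boundary, positive on the solvable side)."""
        ca2 = ca2_at(alpha)
        if unit == 1:
            args = (ca1, ca2, dec1, "C", n1, ca1, problem.theta1)
        else:
            args = (ca2, ca3, dec2, "N", c3, ca3, problem.theta3)
        start, endp, decomp, atom, other, pivot, theta = args
        axis = endp - start
        u = axis / np.linalg.norm(axis)
        e1, e2 = _perp_basis(u)
        x, r, phase = decomp[atom]
        base = start + x * u - pivot
        v = other - pivot
        la = float(np.sqrt(base @ base + r * r))
        target = np.cos(np.deg2rad(theta)) * np.linalg.norm(v) * la
        A = r * (e1 @ v)
        B = r * (e2 @ v)
        D = target - base @ v
        return float(A * A + B * B - D * D)

    grid_vals, grid_v1, grid_v2 = eval_grid(alphas)

    def try_root(root: float, s1: int, s2: int) -> None:
        sol = _assemble(problem, root, s1, s2, ca2_at, dec1, dec2)
        if sol is not None and sol.accepted:
            solutions.append(sol)

    for s1 in (0, 1):
        for s2 in (0, 1):
            F = lambda a: branch_F(a, s1, s2)  # noqa: E731
            vals = [None if np.isnan(v) else float(v) for v in grid_vals[(s1, s2)]]
            for i in range(n_scan):
                a0 = alphas[i]
                a1 = alphas[(i + 1) % n_scan] + (2 * np.pi if i + 1 == n_scan else 0.0)
                f0, f1 = vals[i], vals[(i + 1) % n_scan]
                if f0 is not None and f1 is not None:
                    if f0 == 0.0:
                        try_root(a0, s1, s2)
                    elif f0 * f1 < 0:
                        try:
                            root = brentq(F, a0, a1, xtol=1e-14, rtol=1e-15)
                        except ValueError:
                            continue
                        try_root(root, s1, s2)
                    else:
                        # tangential (double) roots: a small same-sign local
                        # minimum of |F| can hide an exact zero between nodes
                        fm1 = vals[i - 1]
                        if (
                            fm1 is not None
                            and abs(f0) <= abs(fm1)
                            and abs(f0) <= abs(f1)
                            and abs(f0) < 25.0
                            and fm1 * f0 > 0
                        ):
                            lo2 = a0 - (alphas[1] - alphas[0])  # periodic in alpha
                            sgn = 1.0 if f0 > 0 else -1.0

                            def absF(a):
                                fa = F(a)
                                return abs(fa) if fa is not None else 1e6

                            from scipy.optimize import minimize_scalar

                            r = minimize_scalar(
                                absF, bounds=(lo2, a1), method="bounded",
                                options={"xatol": 1e-13},
                            )
                            if r.fun < 1e-3:
                                try_root(float(r.x), s1, s2)
                            elif F(float(r.x)) is not None and sgn * F(float(r.x)) < 0:
                                for lo3, hi3 in ((lo2, float(r.x)), (float(r.x), a1)):
                                    try:
                                        root = brentq(F, lo3, hi3, xtol=1e-14, rtol=1e-15)
                                        try_root(root, s1, s2)
                                    except ValueError:
                                        pass
                elif (f0 is None) != (f1 is None):
                    # branch-validity boundary inside the cell: roots can sit
                    # exactly at the tangency where the two tau roots merge
                    lo, hi = (a0, a1) if f0 is not None else (a1, a0)
                    f_in = f0 if f0 is not None else f1
                    if abs(f_in) > 45.0:
                        # F ~ sqrt near the boundary; a residual this large one
                        # grid cell away cannot reach zero at the tangency
                        continue
                    # locate the validity boundary: it is a zero of the tau
                    # discriminant of whichever unit lost its roots
                    i1 = (i + 1) % n_scan
                    unit = 1 if (grid_v1[i] != grid_v1[i1]) else 2
                    try:
                        a_star = brentq(
                            lambda a: disc(a, unit), min(lo, hi), max(lo, hi),
                            xtol=1e-15, rtol=1e-15,
                        )
                    except ValueError:
                        continue
                    # evaluate F just inside the valid side of the boundary
                    f_edge = None
                    step = (lo - a_star) or 1e-15
                    for frac in (0.0, 1e-12, 1e-9, 1e-6):
                        cand = a_star + frac * step
                        f_edge = F(cand)
                        if f_edge is not None:
                            lo = cand
                            break
                    f_start = vals[i] if vals[i] is not None else vals[i1]
                    a_start = a0 if vals[i] is not None else a1
                    if f_edge is None:
                        continue
                    if f_start * f_edge < 0:
                        try:
                            root = brentq(
                                F, min(a_start, lo), max(a_start, lo), xtol=1e-14, rtol=1e-15
                            )
                            try_root(root, s1, s2)
                        except ValueError:
                            pass
                    elif abs(f_edge) < 1e-3:
                        try_root(lo, s1, s2)

    solutions = _dedupe(solutions)
    solutions.sort(key=lambda s: max(s.residual_bond, s.residual_angle))
    return solutions[:MAX_SOLUTIONS]


def _assemble(
    problem: ClosureProblem, alpha: float, s1: int, s2: int, ca2_at, dec1, dec2
) -> ClosureSolution | None:
    c0, n1, ca1 = (np.asarray(p, dtype=float) for p in problem.n_frame)
    n_a, ca3, c3 = (np.asarray(p, dtype=float) for p in problem.c_frame)
    ca2 = ca2_at(alpha)
    t1 = _tau_roots(ca1, ca2, dec1, "C", n1, ca1, problem.theta1)
    t2 = _tau_roots(ca2, ca3, dec2, "N", c3, ca3, problem.theta3)
    if not t1 or not t2:
        return None
    u1 = _place_unit(ca1, ca2, dec1, t1[s1])
    u2 = _place_unit(ca2, ca3, dec2, t2[s2])
    c1, n2 = u1["C"], u1["N"]
    c2, n3 = u2["C"], u2["N"]
    geo = chemistry.backbone_geometry()
    o_geom = geo.geom_o()
    o1 = place_atom(Frame(n2, ca1, c1), o_geom, 180.0)
    o2 = place_atom(Frame(n3, ca2, c2), o_geom, 180.0)

    atoms = {"C1": c1, "O1": o1, "N2": n2, "CA2": ca2, "C2": c2, "O2": o2, "N3": n3}
    try:
        dihedrals = {
            "phi1": measure_dihedral(c0, n1, ca1, c1),
            "psi1": measure_dihedral(n1, ca1, c1, n2),
            "phi2": measure_dihedral(c1, n2, ca2, c2),
            "psi2": measure_dihedral(n2, ca2, c2, n3),
            "phi3": measure_dihedral(c2, n3, ca3, c3),
            "psi3": float("nan"),  # needs an atom beyond the anchor C
        }
    except GeometryError:
        return None

    # forward verification of the junction against the problem's targets
    u2g = problem.unit2
    res_bond = max(
        abs(np.linalg.norm(c2 - n3) - u2g.b_c_n),
        abs(np.linalg.norm(n3 - ca3) - u2g.b_n_ca),
        abs(np.linalg.norm(ca2 - c2) - u2g.b_ca_c),
    )
    res_angle = max(
        abs(measure_angle(ca2, c2, n3) - u2g.ang_ca_c_n),
        abs(measure_angle(c2, n3, ca3) - u2g.ang_c_n_ca),
        abs(measure_angle(n3, ca3, c3) - problem.theta3),
        abs(measure_angle(u1["N"], ca2, c2) - problem.theta2),
        abs(measure_angle(n1, ca1, c1) - problem.theta1),
        abs(abs(wrap_degrees(measure_dihedral(ca2, c2, n3, ca3))) - abs(wrap_degrees(u2g.omega))),
    )
    return ClosureSolution(
        dihedrals=dihedrals,
        atoms=atoms,
        residual_bond=float(res_bond),
        residual_angle=float(res_angle),
    )


def _dedupe(solutions: list[ClosureSolution], tol: float = 1e-5) -> list[ClosureSolution]:
    kept: list[ClosureSolution] = []
    for s in solutions:
        dup = False
        for k in kept:
            if all(
                np.linalg.norm(s.atoms[n] - k.atoms[n]) < tol for n in ("C1", "CA2", "C2")
            ):
                dup = True
                break
        if not dup:
            kept.append(s)
    return kept


def perturbed_closure(
    problem: ClosureProblem, n_attempts: int, rng: np.random.Generator
) -> tuple[list[ClosureSolution], ClosureProblem]:
    """Attempt closure; re-try with fresh Gaussian geometry jitter until a
    non-empty solution list appears. Attempt 1 is unperturbed. Returns the
    solutions and the (possibly jittered) problem actually solved."""
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    js = problem.jitter
    for attempt in range(n_attempts):
        if attempt == 0:
            trial = problem
        else:
            def jb(v):  # bond
                return v + rng.normal(0.0, js.sigma_bond)

            def ja(v):  # angle
                return v + rng.normal(0.0, js.sigma_angle)

            def jo(v):  # omega
                return v + rng.normal(0.0, js.sigma_omega)

            trial = replace(
                problem,
                unit1=UnitGeometry(
                    jb(problem.unit1.b_ca_c), ja(problem.unit1.ang_ca_c_n),
                    jb(problem.unit1.b_c_n), jo(problem.unit1.omega),
                    ja(problem.unit1.ang_c_n_ca), jb(problem.unit1.b_n_ca),
                ),
                unit2=UnitGeometry(
                    jb(problem.unit2.b_ca_c), ja(problem.unit2.ang_ca_c_n),
                    jb(problem.unit2.b_c_n), jo(problem.unit2.omega),
                    ja(problem.unit2.ang_c_n_ca), jb(problem.unit2.b_n_ca),
                ),
                theta1=ja(problem.theta1),
                theta2=ja(problem.theta2),
            )
        sols = [s for s in solve_closure(trial) if s.accepted]
        if sols:
            return sols, trial
    raise ClosureFailure(f"no closure solution in {n_attempts} attempts")


def select_closure(
    solutions: list[ClosureSolution],
    energies: np.ndarray,
    temperature: float,
    rng: np.random.Generator,
) -> int:
    """Boltzmann-select one solution index given per-solution fragment
    energies (computed by the caller with the potential)."""
    if len(solutions) == 0:
        raise ValueError("empty solution list")
    e = np.asarray(energies, dtype=float)
    w = np.exp(-(e - e.min()) / temperature)
    p = w / w.sum()
    return int(rng.choice(len(solutions), p=p))
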