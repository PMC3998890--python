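"""Distance-guided sequential chain-growth sampling of loop conformations.

One growth step extends the chain by one residue: the C atom is placed by
drawing its anchor distance from the separation-conditional KDE (given the
current Cα-anchor distance) and intersecting the resulting sphere with the
dihedral circle; the next N is placed the same way conditioned on the C
distance; the next Cα follows from an ω dihedral drawn from Normal(180°, σ).
Each of the m trial placements implies a (φ, ψ) pair; a k-subset is kept with
probability proportional to the residue type's empirical (φ, ψ) frequency,
and one survivor is selected with Boltzmann weight exp(-E/T), where E is the
interaction energy of the four new backbone atoms with the fixed protein and
the previously grown loop atoms. When the growing end is three residues from
the C-terminal anchor N, analytic closure generates the remaining backbone.
Side chains are built afterwards from empirical rotamer tables, with residual
steric clashes removed by rotating about χ1 (χ2 for proline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .bundle import ModelBundle
from .closure import (
    ClosureFailure,
    ClosureProblem,
    ClosureSolution,
    JitterSpec,
    perturbed_closure,
    select_closure,
)
from .empirical_models import (
    SamplingError,
    sample_conditional_in_range,
    sample_conditional_in_range_rows,
    select_k_trials,
)
from .geometry import GeometryError, backbone_rmsd, measure_dihedral
from .loopdb_io import Residue, Structure
from .potential import (
    AtomSet,
    PairPotential,
    atoms_from_residues,
    environment_atom_set,
    fragment_energy,
    pair_energy,
    score_loop,
)
from .redcell import (
    DEFAULT_C,
    LoopEllipsoid,
    build_ellipsoid,
    environment_residue_filter,
    prune_growth,
)

BACKBONE_4 = ("N", "CA", "C", "O")
BACKBONE_3 = ("N", "CA", "C")


class SamplingFailure(RuntimeError):
    def __init__(self, message: str, histogram: dict[str, int] | None = None):
        super().__init__(message)
        self.histogram = histogram or {}


@dataclass(frozen=True)
class SamplerConfig:
    """Tunable knobs of the growth engine (all recorded in run metadata)."""

    m: int = 32  # distance-guided trials per step
    k: int = 8  # dihedral-filtered subset size
    temperature: float = 1.0
    omega_sigma: float = 5.0  # degrees about the trans peptide mean of 180
    sidechain_trials: int = 16
    closure_attempts: int = 3  # jitter rescues marginal reach, not bad approach
    closure_jitter: JitterSpec = field(default_factory=JitterSpec)
    max_restarts: int = 100
    clash_ratio: float = 0.7
    clash_rotation_step: float = 30.0  # degrees per clash-resolution rotation
    clash_max_sweeps: int = 12
    redcell_c: float = DEFAULT_C
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.k <= self.m):
            raise ValueError("need 1 <= k <= m")
        if self.temperature <= 0 or self.omega_sigma <= 0:
            raise ValueError("temperature and omega sigma must be positive")


@dataclass
class LoopSpec:
    chain_id: str
    start: int  # chain-internal residue index of the first loop residue
    end: int  # inclusive
    sequence: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LoopConformation:
    """A sampled loop: full heavy-atom residues, energies and bookkeeping."""

    residues: list[Residue]
    start: int
    end: int
    chain_id: str
    energy: float = float("nan")
    backbone_energy: float = float("nan")
    closure_residual_bond: float = float("nan")
    closure_residual_angle: float = float("nan")
    dihedrals: list[dict] = field(default_factory=list)
    rebuilt_anchor_n: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def backbone_coords(self, atoms=BACKBONE_4) -> np.ndarray:
        return np.array([r.atoms[a] for r in self.residues for a in atoms])


def loop_spec_from_author_numbers(
    structure: Structure, chain_id: str, first: int, last: int
) -> LoopSpec:
    chain = structure.chain(chain_id)
    nums = [r.seqnum for r in chain.residues]
    try:
        s, e = nums.index(first), nums.index(last)
    except ValueError as exc:
        raise KeyError(f"residues {first}-{last} not in chain {chain_id}") from exc
    return LoopSpec(chain_id, s, e, [r.name for r in chain.residues[s : e + 1]])


# ---------------------------------------------------------------------------
# growth machinery


class _Growth:
    """Mutable growth state for one sampling attempt."""

    def __init__(self, ctx: "_Context", rng: np.random.Generator):
        self.ctx = ctx
        self.rng = rng
        self.coords: dict[int, dict[str, np.ndarray]] = {
            i: {} for i in range(ctx.spec.start, ctx.spec.end + 1)
        }
        self.grown = AtomSet.empty()
        self.energy = 0.0

    def context_atoms(self) -> AtomSet:
        return AtomSet.concat([self.ctx.env, self.grown])

    def add_fragment(self, res_atoms: list[tuple[int, str, np.ndarray]], energy: float) -> None:
        frag = self.ctx.atom_set(res_atoms)
        self.grown = AtomSet.concat([self.grown, frag])
        self.energy += energy


class _Context:
    """Per-target precomputation shared by all samples: environment atom set,
    ellipsoid, anchors, geometry accessors."""

    def __init__(
        self,
        structure: Structure,
        spec: LoopSpec,
        bundle: ModelBundle,
        config: SamplerConfig,
    ):
        self.structure = structure
        self.spec = spec
        self.bundle = bundle
        self.config = config
        self.chain = structure.chain(spec.chain_id)
        self.chain_index = [c.chain_id for c in structure.chains].index(spec.chain_id)
        if spec.length < 2:
            raise ValueError("loops shorter than 2 residues cannot be closed")
        if spec.start < 1 or spec.end + 1 >= len(self.chain.residues):
            raise ValueError("loop must be interior (anchors on both sides)")
        self.types = [self.chain.residues[i].name for i in range(spec.start, spec.end + 1)]
        if spec.sequence and list(spec.sequence) != self.types:
            self.types = list(spec.sequence)
        prev = self.chain.residues[spec.start - 1]
        nxt = self.chain.residues[spec.end + 1]
        self.prev_res = prev
        self.next_res = nxt
        self.anchor = nxt.coord("N")
        d_cut = bundle.potential.spec.r_hi if bundle.potential else 8.0
        self.ellipsoid: LoopEllipsoid = build_ellipsoid(
            prev.coord("C"), self.anchor, self.types, d_cut=d_cut
        )
        keep = environment_residue_filter(
            structure, spec.chain_id, spec.start, spec.end,
            self.ellipsoid, bundle.radius_table, config.redcell_c, self.types,
        )
        self.env = environment_atom_set(
            structure, spec.chain_id, spec.start, spec.end, keep=keep
        )
        self.geo = chemistry.backbone_geometry()

    def atom_set(self, res_atoms: list[tuple[int, str, np.ndarray]]) -> AtomSet:
        from .potential import _NAME_CODES, atom_type_scheme

        scheme = atom_type_scheme()
        pos, types, keys, codes = [], [], [], []
        for ridx, name, xyz in res_atoms:
            restype = (
                self.types[ridx - self.spec.start]
                if self.spec.start <= ridx <= self.spec.end
                else self.chain.residues[ridx].name
            )
            types.append(scheme.assign(restype, name))
            pos.append(xyz)
            keys.append(self.chain_index * 100000 + ridx)
            codes.append(_NAME_CODES.get(name, 4))
        return AtomSet(
            np.asarray(pos, dtype=float),
            np.asarray(types, dtype=int),
            np.asarray(keys, dtype=int),
            np.asarray(codes, dtype=int),
        )


def _intersect_many(
    circle_center: np.ndarray,
    circle_radius: float,
    circle_normal: np.ndarray,
    anchor: np.ndarray,
    dists: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized circle/sphere intersection for many target distances;
    for each feasible distance one of the (up to) two points is chosen
    uniformly. Returns (mask, points)."""
    w = anchor - circle_center
    h = float(w @ circle_normal)
    w_in = w - h * circle_normal
    rho = float(np.linalg.norm(w_in))
    r = circle_radius
    out = np.zeros((len(dists), 3))
    if rho < 1e-9:
        return np.zeros(len(dists), dtype=bool), out
    cos_t = (r * r + rho * rho + h * h - dists * dists) / (2.0 * r * rho)
    mask = np.abs(cos_t) <= 1.0
    t = np.arccos(np.clip(cos_t, -1.0, 1.0))
    sign = np.where(rng.random(len(dists)) < 0.5, 1.0, -1.0)
    e1 = w_in / rho
    e2 = np.cross(circle_normal, e1)
    out = (
        circle_center
        + r * np.cos(t)[:, None] * e1
        + r * (sign * np.sin(t))[:, None] * e2
    )
    return mask, out


def _rows_unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _cross_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1],
            a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2],
            a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0],
        ],
        axis=-1,
    )


def _place_rows(a, b, c, bond: float, angle_deg: float, dihedrals_deg) -> np.ndarray:
    """Row-wise NeRF placement: one new atom per frame row (a, b, c)."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    c = np.atleast_2d(c)
    bc = _rows_unit(c - b)
    n = _cross_rows(b - a, bc)
    n = _rows_unit(n)
    mvec = _cross_rows(n, bc)
    theta = np.deg2rad(angle_deg)
    tau = np.deg2rad(np.asarray(dihedrals_deg, dtype=float))
    return (
        c
        - bond * np.cos(theta) * bc
        + (bond * np.sin(theta) * np.cos(tau))[:, None] * mvec
        + (bond * np.sin(theta) * np.sin(tau))[:, None] * n
    )


def _dihedral_rows(a, b, c, d) -> np.ndarray:
    """Row-wise dihedrals in degrees, NaN for degenerate rows."""
    b0 = np.atleast_2d(b) - np.atleast_2d(a)
    b1 = np.atleast_2d(c) - np.atleast_2d(b)
    b2 = np.atleast_2d(d) - np.atleast_2d(c)
    n1 = _cross_rows(b0, b1)
    n2 = _cross_rows(b1, b2)
    b1u = _rows_unit(b1)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", _cross_rows(n1, n2), b1u)
    bad = (np.linalg.norm(n1, axis=1) < 1e-9) | (np.linalg.norm(n2, axis=1) < 1e-9)
    out = np.rad2deg(np.arctan2(y, x))
    out = (out + 180.0) % 360.0 - 180.0
    out[bad] = np.nan
    return out


def _circles_rows(prev2, prev1, geom) -> tuple[np.ndarray, float, np.ndarray]:
    """Row-wise placement circles: (centers, radius, normals)."""
    normals = _rows_unit(np.atleast_2d(prev1) - np.atleast_2d(prev2))
    theta = np.deg2rad(geom.bond_angle)
    h = -geom.bond_length * np.cos(theta)
    radius = geom.bond_length * np.sin(theta)
    centers = np.atleast_2d(prev1) + h * normals
    return centers, float(radius), normals


def _band_rows(centers, radius, normals, anchor):
    """Row-wise reachable |P - anchor| bands; (lo, hi, valid)."""
    w = anchor - centers
    h = np.einsum("ij,ij->i", w, normals)
    w_in = w - h[:, None] * normals
    rho = np.linalg.norm(w_in, axis=1)
    valid = rho >= 1e-9
    lo = np.hypot(h, rho - radius)
    hi = np.hypot(h, rho + radius)
    pad = 1e-9 * np.maximum(1.0, hi)
    return lo + pad, hi - pad, valid


def _intersect_rows(centers, radius, normals, anchor, dists, rng):
    """Row-wise circle/sphere intersection, one target distance per row;
    one of the two mirror points chosen uniformly. Returns (mask, points)."""
    w = anchor - centers
    h = np.einsum("ij,ij->i", w, normals)
    w_in = w - h[:, None] * normals
    rho = np.linalg.norm(w_in, axis=1)
    ok = rho >= 1e-9
    rho_safe = np.where(ok, rho, 1.0)
    cos_t = (radius**2 + rho**2 + h**2 - np.asarray(dists) ** 2) / (
        2.0 * radius * rho_safe
    )
    ok &= np.abs(cos_t) <= 1.0
    t = np.arccos(np.clip(cos_t, -1.0, 1.0))
    sign = np.where(rng.random(len(centers)) < 0.5, 1.0, -1.0)
    e1 = w_in / rho_safe[:, None]
    e2 = _cross_rows(normals, e1)
    pts = (
        centers
        + radius * np.cos(t)[:, None] * e1
        + radius * (sign * np.sin(t))[:, None] * e2
    )
    return ok, pts


def _feasible_band(circ, anchor) -> tuple[float, float] | None:
    """Reachable [lo, hi] interval of |P - anchor| for P on the circle."""
    w = anchor - circ.center
    h = float(w @ circ.normal)
    w_in = w - h * circ.normal
    rho = float(np.linalg.norm(w_in))
    if rho < 1e-9:
        return None
    r = circ.radius
    lo = float(np.hypot(h, rho - r))
    hi = float(np.hypot(h, rho + r))
    pad = 1e-9 * max(1.0, hi)
    return lo + pad, hi - pad


def _sample_feasible_distances(kde, d_prev: float, circ, anchor, m: int, rng):
    """Draw m anchor distances from the conditional slice restricted to the
    geometrically reachable band of the placement circle; returns
    (mask, points). Falls back to uniform draws over the band when the
    empirical slice carries no mass there."""
    band = _feasible_band(circ, anchor)
    if band is None:
        return np.zeros(m, dtype=bool), np.zeros((m, 3))
    lo, hi = band
    try:
        d = np.atleast_1d(
            sample_conditional_in_range(kde, d_prev, lo, hi, rng, size=m)
        )
    except SamplingError:
        d = rng.uniform(lo, hi, size=m)
    return _intersect_many(circ.center, circ.radius, circ.normal, anchor, d, rng)


def _batch_fragment_energies(
    ctx: "_Context", frag_entries: list[list[tuple[int, str, np.ndarray]]], context: AtomSet
) -> np.ndarray:
    """Fragment energies of several same-shape trial fragments against one
    shared context, in a single distance computation."""
    pot = ctx.bundle.potential
    if pot is None:
        return np.zeros(len(frag_entries))
    k = len(frag_entries)
    fsize = len(frag_entries[0])
    big = ctx.atom_set([e for frag in frag_entries for e in frag])
    from .potential import _excluded

    out = np.zeros(k)
    if len(context):
        d = np.linalg.norm(big.pos[:, None, :] - context.pos[None, :, :], axis=-1)
        mask, bins = pot.spec.bins_of(d)
        one = AtomSet(big.pos[:fsize], big.types[:fsize], big.res_key[:fsize], big.name_code[:fsize])
        excl = _excluded(one, context)  # identical for every trial fragment
        mask &= ~np.tile(excl, (k, 1))
        e = np.where(mask, pot.energy[np.repeat(big.types[:, None], len(context), 1), context.types[None, :], bins], 0.0)
        out += e.reshape(k, fsize, -1).sum(axis=(1, 2))
    # intra-fragment pairs (same exclusions as the scorer)
    for i, frag in enumerate(frag_entries):
        fs = ctx.atom_set(frag)
        out[i] += pair_energy(pot, fs, fs, same_set=True)
    return out


def _grow_one_residue(
    growth: _Growth, j: int, rng: np.random.Generator, close_after: bool = False
) -> "ClosureSolution | None":
    """Place C_j, O_j, N_{j+1}, CA_{j+1} (the generic growth step).

    With ``close_after`` (the final growth step) the Boltzmann-ranked
    candidates are tried in turn until one admits an analytic closure; the
    closure solution is committed together with the winning trial."""
    ctx = growth.ctx
    cfg = ctx.config
    spec = ctx.spec
    geo = ctx.geo
    type_j = ctx.types[j - spec.start]
    type_next = (
        ctx.types[j + 1 - spec.start] if j + 1 <= spec.end else ctx.next_res.name
    )
    n_j = growth.coords[j]["N"]
    ca_j = growth.coords[j]["CA"]
    prev_c = (
        growth.coords[j - 1]["C"] if j - 1 >= spec.start else ctx.prev_res.coord("C")
    )
    anchor = ctx.anchor
    g = spec.end - j + 1

    # --- C_j trials: distance-guided on the phi circle
    from .geometry import placement_circle

    circ_c = placement_circle(n_j, ca_j, geo.geom_c(type_j))
    d_prev_c = float(np.linalg.norm(ca_j - anchor))
    kde_c = ctx.bundle.kde_for("C", g)
    ok, c_pts = _sample_feasible_distances(kde_c, d_prev_c, circ_c, anchor, cfg.m, rng)

    # --- N_{j+1} trials conditioned on each trial's C distance (row-wise)
    kde_n = ctx.bundle.kde_for("N", max(1, g - 1))
    centers, radius, normals = _circles_rows(ca_j, c_pts, geo.geom_n())
    d_prev_n = np.linalg.norm(c_pts - anchor, axis=1)
    lo, hi, band_ok = _band_rows(centers, radius, normals, anchor)
    d_n, _ = sample_conditional_in_range_rows(
        kde_n, d_prev_n, np.maximum(lo, 1e-6), np.maximum(hi, 2e-6), rng
    )
    m_n, n_pts = _intersect_rows(centers, radius, normals, anchor, d_n, rng)
    ok &= band_ok & m_n

    # --- CA_{j+1} by omega ~ Normal(180, sigma); O_j by standard geometry
    omegas = rng.normal(180.0, cfg.omega_sigma, size=cfg.m)
    geom_ca = geo.geom_ca(type_next)
    geom_o = geo.geom_o()
    with np.errstate(invalid="ignore", divide="ignore"):
        ca_pts = _place_rows(
            np.broadcast_to(ca_j, c_pts.shape), c_pts, n_pts,
            geom_ca.bond_length, geom_ca.bond_angle, omegas,
        )
        o_pts = _place_rows(
            n_pts, np.broadcast_to(ca_j, c_pts.shape), c_pts,
            geom_o.bond_length, geom_o.bond_angle, np.full(cfg.m, 180.0),
        )
        phis = _dihedral_rows(
            np.broadcast_to(prev_c, c_pts.shape), np.broadcast_to(n_j, c_pts.shape),
            np.broadcast_to(ca_j, c_pts.shape), c_pts,
        )
        psis = _dihedral_rows(
            np.broadcast_to(n_j, c_pts.shape), np.broadcast_to(ca_j, c_pts.shape),
            c_pts, n_pts,
        )
    ok &= np.isfinite(phis) & np.isfinite(psis)
    ok &= np.all(np.isfinite(ca_pts), axis=1) & np.all(np.isfinite(o_pts), axis=1)

    # ellipsoid pruning of the whole fragment
    frag_pts = np.stack([c_pts, o_pts, n_pts, ca_pts], axis=1)
    inside = ctx.ellipsoid.contains(frag_pts.reshape(-1, 3)).reshape(cfg.m, 4)
    ok &= inside.all(axis=1)

    idx = np.nonzero(ok)[0]
    if len(idx) == 0:
        raise _StepFailure(f"step {j}: all {cfg.m} trials infeasible")

    # --- dihedral-table subset selection m -> k
    table = ctx.bundle.dihedral_tables.get(type_j)
    if table is not None and len(idx) > cfg.k:
        sel = select_k_trials(phis[idx], psis[idx], table, cfg.k, rng)
        idx = idx[np.sort(sel)]

    # --- Boltzmann selection by fragment energy
    context = growth.context_atoms()
    frag_entries = [
        [
            (j, "C", c_pts[t]),
            (j, "O", o_pts[t]),
            (j + 1, "N", n_pts[t]),
            (j + 1, "CA", ca_pts[t]),
        ]
        for t in idx
    ]
    energies = _batch_fragment_energies(ctx, frag_entries, context)
    weights = np.exp(-(energies - energies.min()) / cfg.temperature)

    def commit(which: int) -> None:
        t = idx[which]
        growth.coords[j]["C"] = c_pts[t]
        growth.coords[j]["O"] = o_pts[t]
        growth.coords[j + 1]["N"] = n_pts[t]
        growth.coords[j + 1]["CA"] = ca_pts[t]
        growth.add_fragment(frag_entries[which], float(energies[which]))

    if not close_after:
        pick = int(rng.choice(len(idx), p=weights / weights.sum()))
        commit(pick)
        return None

    # closure-aware final step: try candidates in Boltzmann order
    w = weights.copy()
    while w.sum() > 0:
        pick = int(rng.choice(len(idx), p=w / w.sum()))
        w[pick] = 0.0
        t = idx[pick]
        try:
            sols = _closure_solutions(
                ctx, c_pts[t], n_pts[t], ca_pts[t], rng
            )
        except (ClosureFailure, GeometryError):
            continue
        commit(pick)
        return _select_and_commit_closure(growth, sols, rng)
    raise _StepFailure(f"closure: no candidate of step {j} admits a closure")


def _closure_solutions(ctx, c_last, n_last, ca_last, rng):
    """Closure solutions for the state whose last grown atoms are
    (C_{e-2}, N_{e-1}, CA_{e-1}); pruned by the loop ellipsoid."""
    spec = ctx.spec
    e = spec.end
    problem = ClosureProblem(
        n_frame=(c_last, n_last, ca_last),
        c_frame=(ctx.anchor, ctx.next_res.coord("CA"), ctx.next_res.coord("C")),
        residue_types=(
            ctx.types[e - 1 - spec.start], ctx.types[e - spec.start], ctx.next_res.name,
        ),
        jitter=ctx.config.closure_jitter,
    )
    sols, _ = perturbed_closure(problem, ctx.config.closure_attempts, rng)
    sols = [
        s
        for s in sols
        if all(
            prune_growth(s.atoms[a], ctx.ellipsoid)
            for a in ("C1", "O1", "N2", "CA2", "C2", "O2")
        )
    ]
    if not sols:
        raise ClosureFailure("all closure solutions pruned by the ellipsoid")
    return sols


def _select_and_commit_closure(growth: _Growth, sols, rng) -> ClosureSolution:
    ctx = growth.ctx
    e = ctx.spec.end
    context = growth.context_atoms()
    entries = [
        [
            (e - 1, "C", s.atoms["C1"]),
            (e - 1, "O", s.atoms["O1"]),
            (e, "N", s.atoms["N2"]),
            (e, "CA", s.atoms["CA2"]),
            (e, "C", s.atoms["C2"]),
            (e, "O", s.atoms["O2"]),
        ]
        for s in sols
    ]
    energies = _batch_fragment_energies(ctx, entries, context)
    pick = select_closure(sols, energies, ctx.config.temperature, rng)
    sol = sols[pick]
    growth.coords[e - 1]["C"] = sol.atoms["C1"]
    growth.coords[e - 1]["O"] = sol.atoms["O1"]
    growth.coords[e]["N"] = sol.atoms["N2"]
    growth.coords[e]["CA"] = sol.atoms["CA2"]
    growth.coords[e]["C"] = sol.atoms["C2"]
    growth.coords[e]["O"] = sol.atoms["O2"]
    growth.add_fragment(entries[pick], float(energies[pick]))
    return sol


def _initial_step(growth: _Growth, rng: np.random.Generator) -> None:
    """Place N and Cα of the first loop residue from the N-side anchor."""
    ctx = growth.ctx
    cfg = ctx.config
    spec = ctx.spec
    geo = ctx.geo
    from .geometry import placement_circle

    prev = ctx.prev_res
    s = spec.start
    type_s = ctx.types[0]
    anchor = ctx.anchor
    circ_n = placement_circle(prev.coord("CA"), prev.coord("C"), geo.geom_n())
    d_prev = float(np.linalg.norm(prev.coord("C") - anchor))
    kde = ctx.bundle.kde_for("N", spec.length)
    ok, n_pts = _sample_feasible_distances(kde, d_prev, circ_n, anchor, cfg.m, rng)
    geom_ca = geo.geom_ca(type_s)
    omegas = rng.normal(180.0, cfg.omega_sigma, size=cfg.m)
    with np.errstate(invalid="ignore", divide="ignore"):
        ca_pts = _place_rows(
            np.broadcast_to(prev.coord("CA"), n_pts.shape),
            np.broadcast_to(prev.coord("C"), n_pts.shape),
            n_pts, geom_ca.bond_length, geom_ca.bond_angle, omegas,
        )
        psis = _dihedral_rows(
            np.broadcast_to(prev.coord("N"), n_pts.shape),
            np.broadcast_to(prev.coord("CA"), n_pts.shape),
            np.broadcast_to(prev.coord("C"), n_pts.shape), n_pts,
        )
    ok &= np.isfinite(psis) & np.all(np.isfinite(ca_pts), axis=1)
    pts = np.stack([n_pts, ca_pts], axis=1)
    ok &= ctx.ellipsoid.contains(pts.reshape(-1, 3)).reshape(cfg.m, 2).all(axis=1)
    idx = np.nonzero(ok)[0]
    if len(idx) == 0:
        raise _StepFailure("initial step: all trials infeasible")
    phi_prev = (
        measure_dihedral(
            ctx.chain.residues[s - 2].coord("C"),
            prev.coord("N"), prev.coord("CA"), prev.coord("C"),
        )
        if s >= 2
        else 0.0
    )
    table = ctx.bundle.dihedral_tables.get(prev.name)
    if table is not None and len(idx) > cfg.k:
        sel = select_k_trials(
            np.full(len(idx), phi_prev), psis[idx], table, cfg.k, rng
        )
        idx = idx[np.sort(sel)]
    context = growth.context_atoms()
    frag_entries = [[(s, "N", n_pts[t]), (s, "CA", ca_pts[t])] for t in idx]
    energies = _batch_fragment_energies(ctx, frag_entries, context)
    w = np.exp(-(energies - energies.min()) / cfg.temperature)
    pick = int(rng.choice(len(idx), p=w / w.sum()))
    t = idx[pick]
    growth.coords[s]["N"] = n_pts[t]
    growth.coords[s]["CA"] = ca_pts[t]
    growth.add_fragment(
        [(s, "N", n_pts[t]), (s, "CA", ca_pts[t])], float(energies[pick])
    )


class _StepFailure(RuntimeError):
    pass


def _close_loop(growth: _Growth, rng: np.random.Generator) -> ClosureSolution:
    """Closure from the current growth state (short loops with no final
    growth step)."""
    ctx = growth.ctx
    spec = ctx.spec
    e = spec.end
    c_prev = (
        growth.coords[e - 2]["C"] if e - 2 >= spec.start else ctx.prev_res.coord("C")
    )
    try:
        sols = _closure_solutions(
            ctx, c_prev, growth.coords[e - 1]["N"], growth.coords[e - 1]["CA"], rng
        )
    except ClosureFailure as exc:
        raise _StepFailure(str(exc)) from exc
    return _select_and_commit_closure(growth, sols, rng)


def sample_loop(
    structure: Structure,
    spec: LoopSpec,
    bundle: ModelBundle,
    config: SamplerConfig,
    rng: np.random.Generator,
    _ctx: "_Context | None" = None,
) -> LoopConformation:
    """Grow one closed, backbone-complete loop conformation (no side chains).

    Raises :class:`SamplingFailure` when the restart budget is exhausted."""
    ctx = _ctx or _Context(structure, spec, bundle, config)
    histogram: dict[str, int] = {}
    for _ in range(config.max_restarts):
        growth = _Growth(ctx, rng)
        try:
            _initial_step(growth, rng)
            sol = None
            for j in range(spec.start, spec.end - 1):
                sol = _grow_one_residue(
                    growth, j, rng, close_after=(j == spec.end - 2)
                )
            if sol is None:  # 2-residue loop: no growth step, close directly
                sol = _close_loop(growth, rng)
        except (_StepFailure, ClosureFailure, SamplingError) as exc:
            key = str(exc).split(":")[0]
            histogram[key] = histogram.get(key, 0) + 1
            continue
        residues = []
        for i in range(spec.start, spec.end + 1):
            r = Residue(ctx.types[i - spec.start], ctx.chain.residues[i].seqnum)
            r.atoms = {k: np.asarray(v) for k, v in growth.coords[i].items()}
            residues.append(r)
        conf = LoopConformation(
            residues=residues,
            start=spec.start,
            end=spec.end,
            chain_id=spec.chain_id,
            backbone_energy=growth.energy,
            energy=growth.energy,
            closure_residual_bond=sol.residual_bond,
            closure_residual_angle=sol.residual_angle,
            rebuilt_anchor_n=sol.atoms["N3"],
        )
        return conf
    raise SamplingFailure(
        f"no closed conformation within {config.max_restarts} restarts", histogram
    )


# ---------------------------------------------------------------------------
# side chains


def _rotate_about(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(deg)
    k = axis
    p = points - origin
    return (
        origin
        + p * np.cos(th)
        + np.cross(k, p) * np.sin(th)
        + k * (p @ k)[:, None] * (1 - np.cos(th))
    )


def build_side_chains(
    conformation: LoopConformation,
    structure: Structure,
    bundle: ModelBundle,
    config: SamplerConfig,
    rng: np.random.Generator,
    _ctx: "_Context | None" = None,
) -> LoopConformation:
    """Attach side chains residue by residue in growth order: rotamer trials
    from the empirical chi tables, one kept by Boltzmann weight, then clash
    resolution. Backbone coordinates are never touched."""
    ctx = _ctx or _Context(
        structure,
        LoopSpec(conformation.chain_id, conformation.start, conformation.end),
        bundle,
        config,
    )
    grown_entries: list[tuple[int, str, np.ndarray]] = []
    for i, res in enumerate(conformation.residues):
        for name, xyz in res.atoms.items():
            grown_entries.append((conformation.start + i, name, xyz))
    context = AtomSet.concat([ctx.env, ctx.atom_set(grown_entries)])
    total = conformation.backbone_energy
    for i, res in enumerate(conformation.residues):
        nchi = chemistry.n_chi(res.name)
        if res.name == "GLY":
            continue
        table = bundle.chi_tables.get(res.name)
        if nchi == 0 or table is None or not table.bins:
            trials = np.asarray([chemistry.canonical_chi(res.name)])
        else:
            trials = table.sample(rng, size=config.sidechain_trials)
        backbone = {a: res.atoms[a] for a in ("N", "CA", "C")}
        built = [chemistry.build_side_chain(res.name, backbone, chi) for chi in trials]
        frags = [
            ctx.atom_set([(conformation.start + i, n, p) for n, p in b.items()])
            for b in built
        ]
        if bundle.potential is None:
            energies = np.zeros(len(frags))
        else:
            energies = np.array(
                [fragment_energy(f, context, bundle.potential) for f in frags]
            )
        w = np.exp(-(energies - energies.min()) / config.temperature)
        pick = int(rng.choice(len(built), p=w / w.sum()))
        for n, p in built[pick].items():
            res.atoms[n] = p
        context = AtomSet.concat([context, frags[pick]])
        total += float(energies[pick])
    conformation.energy = total
    resolve_clashes(conformation, ctx, rng)
    # re-score after any clash-resolution rotations
    loop_entries = [
        (conformation.start + i, n, p)
        for i, r in enumerate(conformation.residues)
        for n, p in r.atoms.items()
    ]
    loop_atoms = ctx.atom_set(loop_entries)
    if bundle.potential is not None:
        conformation.energy = score_loop(loop_atoms, ctx.env, bundle.potential)
    return conformation


def _clash_pairs(ctx: "_Context", conformation: LoopConformation, ratio: float):
    """Residue indices (loop-internal) of side chains involved in clashes."""
    loop_entries = [
        (conformation.start + i, n, p)
        for i, r in enumerate(conformation.residues)
        for n, p in r.atoms.items()
    ]
    loop_atoms = ctx.atom_set(loop_entries)
    names = [n for (_, n, _) in loop_entries]
    ridx = np.array([k for (k, _, _) in loop_entries])
    radii_loop = np.array([chemistry.vdw_radius(n) for n in names])
    others = AtomSet.concat([ctx.env, loop_atoms])
    # vdW radii for the combined context: env names are not retained in the
    # AtomSet, so recompute element radii from the type table via positions.
    # Instead pair loop atoms against env and loop separately.
    from .potential import _excluded

    clashing: set[int] = set()
    for other, other_radii, same in (
        (ctx.env, ctx.env_radii if hasattr(ctx, "env_radii") else None, False),
        (loop_atoms, radii_loop, True),
    ):
        if other_radii is None:
            other_radii = _env_radii(ctx)
            ctx.env_radii = other_radii  # type: ignore[attr-defined]
        if len(other) == 0 or len(loop_atoms) == 0:
            continue
        d = np.linalg.norm(loop_atoms.pos[:, None, :] - other.pos[None, :, :], axis=-1)
        lim = ratio * (radii_loop[:, None] + other_radii[None, :])
        bad = (d < lim) & ~_excluded(loop_atoms, other)
        if same:
            bad &= ~np.eye(len(loop_atoms), dtype=bool)
        ii, jj = np.nonzero(bad)
        for a, b in zip(ii, jj):
            a_side = names[a] not in ("N", "CA", "C", "O")
            b_side = same and names[b] not in ("N", "CA", "C", "O")
            if a_side:
                clashing.add(int(ridx[a]) - conformation.start)
            if b_side:
                clashing.add(int(ridx[b]) - conformation.start)
            if same and not (a_side or b_side):
                continue  # backbone-backbone proximity is energy-governed
    return clashing


def _env_radii(ctx: "_Context") -> np.ndarray:
    radii = chemistry.atom_type_table()["vdw_radii"]
    # element by type id: backbone N/CA/C/O then side classes by leading letter
    from .potential import atom_type_scheme

    scheme = atom_type_scheme()
    by_type = []
    for name in scheme.type_names:
        if name == "bbN" or name.startswith("N"):
            by_type.append(radii["N"])
        elif name == "bbO" or name.startswith("O"):
            by_type.append(radii["O"])
        elif name == "S":
            by_type.append(radii["S"])
        else:
            by_type.append(radii["C"])
    return np.asarray(by_type)[ctx.env.types]


def _residue_clash_count(
    ctx: "_Context", conformation: LoopConformation, li: int, ratio: float
) -> int:
    """Clashing pairs involving loop residue ``li`` (against the environment
    and the other loop atoms)."""
    res = conformation.residues[li]
    names = [n for n in res.atoms if n not in ("N", "CA", "C", "O")]
    if not names:
        return 0
    pts = np.array([res.atoms[n] for n in names])
    radii = np.array([chemistry.vdw_radius(n) for n in names])
    entries = [(conformation.start + li, n, res.atoms[n]) for n in names]
    me = ctx.atom_set(entries)
    count = 0
    from .potential import _excluded

    other_entries = [
        (conformation.start + i, n, p)
        for i, r in enumerate(conformation.residues)
        if i != li
        for n, p in r.atoms.items()
    ]
    for other, other_radii in (
        (ctx.env, _env_radii(ctx)),
        (
            ctx.atom_set(other_entries),
            np.array([chemistry.vdw_radius(n) for (_, n, _) in other_entries]),
        ),
    ):
        if len(other) == 0:
            continue
        d = np.linalg.norm(pts[:, None] - other.pos[None], axis=-1)
        lim = ratio * (radii[:, None] + other_radii[None])
        count += int(((d < lim) & ~_excluded(me, other)).sum())
    return count


def _movable_side_chain(res):
    """(origin, axis endpoint, movable atom names) for clash rotation."""
    if res.name in ("GLY", "ALA") or "CB" not in res.atoms:
        return None
    if res.name == "PRO":
        if "CG" not in res.atoms:
            return None
        return res.atoms["CB"], res.atoms["CG"], [n for n in res.atoms if n == "CD"]
    movable = [n for n in res.atoms if n not in ("N", "CA", "C", "O", "CB")]
    if not movable:
        return None
    return res.atoms["CA"], res.atoms["CB"], movable


def resolve_clashes(
    conformation: LoopConformation, ctx: "_Context", rng: np.random.Generator
) -> None:
    """Remove steric clashes by side-chain moves: for each clashing residue,
    the best of all χ1 rotations (proline: χ2) is taken; residues that stay
    clashed afterwards are re-built from fresh rotamer draws. Backbone atoms
    never move; a conformation that cannot be cleaned is flagged."""
    cfg = ctx.config
    for sweep in range(cfg.clash_max_sweeps):
        clashing = _clash_pairs(ctx, conformation, cfg.clash_ratio)
        if not clashing:
            if "clash_unresolved" in conformation.flags:
                conformation.flags.remove("clash_unresolved")
            return
        improved = False
        for li in sorted(clashing):
            res = conformation.residues[li]
            move = _movable_side_chain(res)
            if move is None:
                continue
            origin, axis_end, movable = move
            base = np.array([res.atoms[n] for n in movable])
            best_pts = base
            best_count = _residue_clash_count(ctx, conformation, li, cfg.clash_ratio)
            if best_count == 0:
                continue
            n_steps = int(round(360.0 / cfg.clash_rotation_step))
            for k in range(1, n_steps):
                rot = _rotate_about(
                    base, origin, axis_end - origin, cfg.clash_rotation_step * k
                )
                for n, p in zip(movable, rot):
                    res.atoms[n] = p
                count = _residue_clash_count(ctx, conformation, li, cfg.clash_ratio)
                if count < best_count:
                    best_count = count
                    best_pts = rot
                    if count == 0:
                        break
            for n, p in zip(movable, best_pts):
                res.atoms[n] = p
            if best_count == 0:
                improved = True
                continue
            # rotation alone failed: re-draw the whole rotamer
            table = ctx.bundle.chi_tables.get(res.name)
            if table is not None and table.bins:
                backbone = {a: res.atoms[a] for a in ("N", "CA", "C")}
                for chi in table.sample(rng, size=cfg.sidechain_trials):
                    cand = chemistry.build_side_chain(res.name, backbone, chi)
                    saved = {n: res.atoms[n] for n in cand}
                    res.atoms.update(cand)
                    count = _residue_clash_count(
                        ctx, conformation, li, cfg.clash_ratio
                    )
                    if count < best_count:
                        best_count = count
                        saved = None
                        if count == 0:
                            break
                    if saved is not None:
                        res.atoms.update(saved)
            if best_count == 0:
                improved = True
        if not improved and sweep > 0:
            break
    if _clash_pairs(ctx, conformation, cfg.clash_ratio):
        if "clash_unresolved" not in conformation.flags:
            conformation.flags.append("clash_unresolved")


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class Ensemble:
    conformations: list[LoopConformation]
    energies: np.ndarray
    rmsd4: np.ndarray | None
    rmsd3: np.ndarray | None
    failure_histogram: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.conformations)


def sample_ensemble(
    structure: Structure,
    spec: LoopSpec,
    n: int,
    bundle: ModelBundle,
    config: SamplerConfig,
    seed: int,
    native: list[Residue] | None = None,
    with_side_chains: bool = True,
) -> Ensemble:
    """Generate ``n`` closed conformations with per-member split seeds.

    Each member gets its own child RNG stream from the master seed, so
    ensembles are reproducible and prefix-stable: the first n members of a
    larger run equal the smaller run exactly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ctx = _Context(structure, spec, bundle, config)
    seeds = np.random.SeedSequence(seed).spawn(n)
    confs: list[LoopConformation] = []
    hist: dict[str, int] = {}
    failures = 0
    for i in range(n):
        rng = np.random.default_rng(seeds[i])
        try:
            conf = None
            for _ in range(12):  # clash-flagged members are redrawn
                cand = sample_loop(structure, spec, bundle, config, rng, _ctx=ctx)
                if with_side_chains:
                    cand = build_side_chains(cand, structure, bundle, config, rng, _ctx=ctx)
                else:
                    cand.energy = cand.backbone_energy
                conf = cand
                if "clash_unresolved" not in cand.flags:
                    break
                hist["clash_resample"] = hist.get("clash_resample", 0) + 1
            confs.append(conf)
        except SamplingFailure as exc:
            failures += 1
            for k, v in exc.histogram.items():
                hist[k] = hist.get(k, 0) + v
            if failures > 99 * max(1, len(confs)):
                raise SamplingFailure(
                    f"aggregate failure rate above 99% after {failures} failures", hist
                )
    energies = np.array([c.energy for c in confs])
    rmsd4 = rmsd3 = None
    if native is not None:
        nat4 = np.array([r.atoms[a] for r in native for a in BACKBONE_4])
        nat3 = np.array([r.atoms[a] for r in native for a in BACKBONE_3])
        rmsd4 = np.array([backbone_rmsd(nat4, c.backbone_coords(BACKBONE_4)) for c in confs])
        rmsd3 = np.array([backbone_rmsd(nat3, c.backbone_coords(BACKBONE_3)) for c in confs])
    return Ensemble(
        conformations=confs,
        energies=energies,
        rmsd4=rmsd4,
        rmsd3=rmsd3,
        failure_histogram=hist,
        metadata={"seed": seed, "n_requested": n, "config": config.__dict__.copy()},
    )


def rank_and_report(ensemble: Ensemble) -> dict:
    """Ensemble statistics: minimum RMSD, mean RMSD, RMSD of the
    lowest-energy member (ties broken by lower index), and the
    energy-ranked order."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    order = np.lexsort((np.arange(len(ensemble)), ensemble.energies))
    report: dict = {"ranked": order.tolist(), "lowest_energy_index": int(order[0])}
    if ensemble.rmsd4 is not None:
        report.update(
            min_rmsd=float(ensemble.rmsd4.min()),
            ensemble_mean_rmsd=float(ensemble.rmsd4.mean()),
            rmsd_of_lowest_energy=float(ensemble.rmsd4[order[0]]),
        )
    return report
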