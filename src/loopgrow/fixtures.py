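"""Synthetic structure generator.

Builds ideal-geometry polypeptides with a prescribed secondary-structure plan
(helix, strand, coil runs), canonical rotamer side chains and exact trans
peptide bonds, so that every other module can be exercised without any
external structure download. Coil (φ, ψ) pairs are drawn from a mixture of
broad Gaussians centered on the three classic Ramachandran basins, giving the
loop database realistic dispersion with known ground truth.

``make_corpus`` generates a diverse set of such proteins, builds the loop
database, fits all empirical models, generates geometry-only decoys for the
reference state, and returns a ready-to-sample parameter bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .bundle import ModelBundle, fit_bundle
from .empirical_models import DEFAULT_WINSOR_LEVEL
from .geometry import Frame, place_atom, wrap_degrees
from .loopdb_io import (
    Chain,
    LoopDatabase,
    LoopRegion,
    Residue,
    Structure,
    build_loop_db,
    identify_loops,
)
from .potential import (
    BinSpec,
    PairPotential,
    atom_type_scheme,
    build_potential,
    count_expected,
    count_observed,
    environment_atom_set,
    loop_atom_set,
)

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)
# coil basins: (phi, psi, sigma_phi, sigma_psi, weight)
COIL_BASINS = (
    (-63.0, -43.0, 12.0, 12.0, 0.45),
    (-125.0, 135.0, 20.0, 15.0, 0.40),
    (57.0, 47.0, 10.0, 10.0, 0.15),
)
# two-residue beta-turn motifs (types I, I', II, II'): embedding one per coil
# run makes chains fold back on themselves the way real loop regions do
TURN_MOTIFS = (
    ((-60.0, -30.0), (-90.0, 0.0)),
    ((60.0, 30.0), (90.0, 0.0)),
    ((-60.0, 120.0), (80.0, 0.0)),
    ((60.0, -120.0), (-80.0, 0.0)),
)
TURN_SIGMA = 8.0  # degrees of jitter on motif dihedrals
CLASH_RATIO = 0.7  # nonbonded pairs must keep distance/vdW-radius-sum above this
COMPACTNESS_RG = 4.0  # accept when Rg <= COMPACTNESS_RG * n_res^(1/3)
# proline and glycine are left out of generated sequences' loop-adjacent runs
# only through the weighting below; both remain fully supported downstream.
SEQUENCE_WEIGHTS = {aa: (0.2 if aa in ("PRO", "GLY") else 1.0) for aa in chemistry.AMINO_ACIDS}


@dataclass
class FixtureSpec:
    plan: list[tuple[str, int]]  # (label in {H, E, C}, run length)
    sequence: list[str] | None = None
    noise_sigma: float = 0.0  # Å, isotropic Gaussian on all coordinates
    seed: int = 0

    @property
    def n_residues(self) -> int:
        return sum(n for _, n in self.plan)


def _draw_sequence(n: int, rng: np.random.Generator) -> list[str]:
    aas = list(chemistry.AMINO_ACIDS)
    w = np.array([SEQUENCE_WEIGHTS[a] for a in aas])
    return [aas[i] for i in rng.choice(len(aas), size=n, p=w / w.sum())]


def _draw_basin(rng: np.random.Generator) -> tuple[float, float]:
    w = np.array([b[4] for b in COIL_BASINS])
    b = COIL_BASINS[rng.choice(len(COIL_BASINS), p=w / w.sum())]
    return (
        float(wrap_degrees(rng.normal(b[0], b[2]))),
        float(wrap_degrees(rng.normal(b[1], b[3]))),
    )


def _residue_schedule(plan, rng: np.random.Generator) -> list[tuple]:
    """Per-residue dihedral sources: fixed (H/E), a coil basin draw, or a
    jittered turn-motif residue (one two-residue motif embedded per coil
    run)."""
    out: list[tuple] = []
    for lab, ln in plan:
        if lab not in "HEC" or ln < 1:
            raise ValueError(f"bad plan entry {(lab, ln)}")
        if lab == "H":
            out.extend([("fixed", HELIX_PHI_PSI, lab)] * ln)
        elif lab == "E":
            out.extend([("fixed", STRAND_PHI_PSI, lab)] * ln)
        else:
            pos = int(rng.integers(0, ln - 1)) if ln >= 2 else -1
            motif = TURN_MOTIFS[int(rng.choice(len(TURN_MOTIFS)))]
            for k in range(ln):
                if pos >= 0 and k in (pos, pos + 1):
                    out.append(("turn", motif[k - pos], lab))
                else:
                    out.append(("basin", None, lab))
    return out


def _draw_step(kind, params, rng: np.random.Generator) -> tuple[float, float]:
    if kind == "fixed":
        return params
    if kind == "turn":
        return (
            float(wrap_degrees(params[0] + rng.normal(0, TURN_SIGMA))),
            float(wrap_degrees(params[1] + rng.normal(0, TURN_SIGMA))),
        )
    return _draw_basin(rng)


def make_protein(spec: FixtureSpec) -> tuple[Structure, dict[str, dict[int, str]]]:
    """Ideal-geometry polypeptide + its secondary-structure assignment.

    The backbone is built as a self-avoiding walk: helix/strand residues use
    their canonical dihedrals, coil residues redraw (φ, ψ) until the newly
    placed backbone atoms stay off previously placed ones. The whole build
    restarts (deterministically, continuing the seed's stream) when a rigid
    element cannot avoid a clash. Side chains come from canonical rotamers,
    with a χ1 sweep to relieve residual contacts.
    """
    rng = np.random.default_rng(spec.seed)
    labels: list[str] = []
    for lab, ln in spec.plan:
        labels.extend(lab * ln)
    n = len(labels)
    seq = list(spec.sequence) if spec.sequence else _draw_sequence(n, rng)
    if len(seq) != n:
        raise ValueError("sequence length does not match the plan")

    geo = chemistry.backbone_geometry()
    backbone = None
    for _ in range(40):  # whole-structure attempts
        schedule = _residue_schedule(spec.plan, rng)
        backbone = _build_backbone(schedule, seq, geo, rng)
        if backbone is not None:
            break
    if backbone is None:
        raise RuntimeError("could not build a self-avoiding backbone for this plan")

    residues: list[Residue] = []
    placed: list[np.ndarray] = []
    placed_radii: list[float] = []
    for i in range(n):
        res = Residue(seq[i], i + 1)
        res.atoms = dict(backbone[i])
        if res.name != "GLY":
            side = chemistry.build_side_chain(
                res.name,
                {a: res.atoms[a] for a in ("N", "CA", "C")},
                chemistry.canonical_chi(res.name),
            )
            side = _relieve_side_chain(res.name, res.atoms, side, placed, placed_radii, rng)
            res.atoms.update(side)
        placed.extend(res.atoms.values())
        placed_radii.extend(chemistry.vdw_radius(n_) for n_ in res.atoms)
        residues.append(res)

    if spec.noise_sigma > 0:
        for res in residues:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + rng.normal(0, spec.noise_sigma, 3)

    st = Structure(f"fixture{spec.seed:05d}", [Chain("A", residues)])
    assignment = {"A": {r.seqnum: lab for r, lab in zip(residues, labels)}}
    return st, assignment


def _build_backbone(schedule, seq, geo, rng) -> list[dict[str, np.ndarray]] | None:
    """Self-avoiding backbone walk; returns per-residue atom dicts or None."""
    n = len(schedule)
    npos = np.array([0.0, 0.0, 0.0])
    capos = np.array([geo.bonds["N-CA"], 0.0, 0.0])
    atoms: list[dict[str, np.ndarray]] = [{"N": npos, "CA": capos}]
    cloud: list[np.ndarray] = []  # backbone atoms of residues <= i-2
    cloud_radii: list[float] = []
    per_res: list[list[np.ndarray]] = []

    for i in range(n):
        if i >= 2:
            cloud.extend(per_res[i - 2])
            cloud_radii.extend([1.55, 1.70, 1.70, 1.52])
        kind, params, _ = schedule[i]
        tries = 1 if kind == "fixed" else 60
        cur = atoms[i]
        prev_c = atoms[i - 1]["C"] if i > 0 else None
        placedk = None
        for _ in range(tries):
            phi, psi = _draw_step(kind, params, rng)
            if i == 0:
                c = place_atom(
                    Frame(np.array([0.0, 1.0, 0.0]), cur["N"], cur["CA"]),
                    geo.geom_c(seq[0]), 25.0,
                )
            else:
                c = place_atom(
                    Frame(prev_c, cur["N"], cur["CA"]), geo.geom_c(seq[i]), phi
                )
            nxt_n = place_atom(Frame(cur["N"], cur["CA"], c), geo.geom_n(), psi)
            o = place_atom(Frame(nxt_n, cur["CA"], c), geo.geom_o(), 180.0)
            new_pts = [c, o, nxt_n]
            new_radii = [1.70, 1.52, 1.55]
            if i + 1 < n:
                nxt_ca = place_atom(
                    Frame(cur["CA"], c, nxt_n), geo.geom_ca(seq[i + 1]), geo.omega_trans
                )
                new_pts.append(nxt_ca)
                new_radii.append(1.70)
            if cloud:
                d = np.linalg.norm(np.asarray(cloud)[:, None] - np.asarray(new_pts)[None], axis=-1)
                lim = CLASH_RATIO * (
                    np.asarray(cloud_radii)[:, None] + np.asarray(new_radii)[None]
                )
                if np.any(d < lim):
                    continue
            placedk = (c, o, nxt_n, new_pts)
            break
        if placedk is None:
            return None
        c, o, nxt_n, new_pts = placedk
        cur["C"] = c
        cur["O"] = o
        if i + 1 < n:
            atoms.append({"N": nxt_n, "CA": new_pts[3]})
        per_res.append([cur["N"], cur["CA"], c, o])
    return atoms


def _relieve_side_chain(restype, backbone_atoms, side, placed, placed_radii, rng):
    """Rotate χ1 in 30° steps if the canonical rotamer bumps earlier atoms
    (vdW-ratio clash criterion)."""
    if not side or not placed or restype in ("ALA", "GLY") or "CB" not in side:
        return side
    cloud = np.asarray(placed)
    cloud_r = np.asarray(placed_radii)
    chis = chemistry.canonical_chi(restype)

    def worst_ratio(s):
        pts = np.asarray(list(s.values()))
        rr = np.asarray([chemistry.vdw_radius(n) for n in s])
        d = np.linalg.norm(cloud[:, None] - pts[None], axis=-1)
        return float((d / (cloud_r[:, None] + rr[None])).min())

    best, best_q = side, worst_ratio(side)
    if best_q >= CLASH_RATIO or not chis:
        return side
    bb = {a: backbone_atoms[a] for a in ("N", "CA", "C")}
    for k in range(1, 12):
        cand_chi = list(chis)
        cand_chi[0] = chis[0] + 30.0 * k
        cand = chemistry.build_side_chain(restype, bb, cand_chi)
        q = worst_ratio(cand)
        if q > best_q:
            best, best_q = cand, q
        if best_q >= CLASH_RATIO:
            break
    return best


def structure_is_valid(structure: Structure) -> bool:
    """Clash-free (no nonbonded heavy-atom pair below the floor, residues more
    than one apart in sequence) and compact (Rg within the globular band)."""
    chain = structure.chains[0]
    coords, ridx, radii = [], [], []
    for i, res in enumerate(chain.residues):
        for name, p in res.atoms.items():
            coords.append(p)
            ridx.append(i)
            radii.append(chemistry.vdw_radius(name))
    coords = np.asarray(coords)
    ridx = np.asarray(ridx)
    radii = np.asarray(radii)
    cas = np.array([r.atoms["CA"] for r in chain.residues])
    rg = float(np.sqrt(((cas - cas.mean(0)) ** 2).sum(1).mean()))
    if rg > COMPACTNESS_RG * len(cas) ** (1.0 / 3.0):
        return False
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    lim = CLASH_RATIO * (radii[:, None] + radii[None, :])
    nonlocal_mask = np.abs(ridx[:, None] - ridx[None, :]) > 1
    return bool(np.all(d[nonlocal_mask] >= lim[nonlocal_mask]))


def make_packed_protein(
    plan, rng: np.random.Generator, max_tries: int = 600, redraw_plan: bool = True
) -> tuple[Structure, dict[str, dict[int, str]]]:
    """Draw fixture seeds (and, if allowed, fresh plans) until the built
    protein is clash-free and compact."""
    current = plan
    for attempt in range(max_tries):
        spec = FixtureSpec(plan=current, seed=int(rng.integers(0, 2**31 - 1)))
        try:
            st, asn = make_protein(spec)
        except RuntimeError:
            st = None
        if st is not None and structure_is_valid(st):
            return st, asn
        if redraw_plan and attempt % 5 == 4:
            current = random_plan(rng)
    raise RuntimeError(f"no valid packed fixture for plan {plan} in {max_tries} tries")


def make_loop_target(
    structure: Structure, chain_id: str, start: int, end: int
) -> tuple[Structure, "LoopSpecLike", list[Residue]]:
    """Excise a loop: returns (truncated structure, loop spec, native residues).

    ``start``/``end`` are chain-internal residue indices; the region must be
    interior so that both anchors survive."""
    from .sampler import LoopSpec

    chain = structure.chain(chain_id)
    if start < 1 or end + 1 >= len(chain.residues):
        raise ValueError("loop region must not touch a chain terminus")
    native = [
        Residue(r.name, r.seqnum, r.icode, {k: v.copy() for k, v in r.atoms.items()})
        for r in chain.residues[start : end + 1]
    ]
    truncated = structure.copy()
    tchain = truncated.chain(chain_id)
    for i in range(start, end + 1):
        tchain.residues[i].atoms = {}
    spec = LoopSpec(chain_id, start, end, [r.name for r in native])
    return truncated, spec, native


LoopSpecLike = object  # forward-declared return type for make_loop_target


def random_plan(rng: np.random.Generator) -> list[tuple[str, int]]:
    plan = [("H", int(rng.integers(5, 9)))]
    for _ in range(int(rng.integers(2, 4))):
        plan.append(("C", int(rng.integers(4, 10))))
        plan.append(("H" if rng.random() < 0.5 else "E", int(rng.integers(5, 9))))
    return plan


def flat_potential(spec: BinSpec | None = None) -> PairPotential:
    """All-zero energy table (geometry-only growth for reference decoys)."""
    spec = spec or BinSpec()
    n = atom_type_scheme().n_types
    return PairPotential(spec=spec, energy=np.zeros((n, n, spec.n_bins)))


@dataclass
class Corpus:
    entries: list[tuple[Structure, dict]] = field(default_factory=list)
    db: LoopDatabase | None = None
    bundle: ModelBundle | None = None


def make_corpus(
    n_structures: int = 40,
    seed: int = 0,
    n_decoys: int = 3,
    bin_spec: BinSpec | None = None,
    winsor_level: float = DEFAULT_WINSOR_LEVEL,
    min_len: int = 4,
    max_len: int = 12,
) -> Corpus:
    """Generate a corpus, build the loop database, fit every empirical model
    and train the pair potential against geometry-only decoys."""
    from .sampler import LoopSpec, SamplerConfig, SamplingFailure, sample_loop, build_side_chains

    if n_structures < 20:
        raise ValueError("need >= 20 structures for stable KDE fits")
    rng = np.random.default_rng(seed)
    corpus = Corpus()
    for i in range(n_structures):
        st, asn = make_packed_protein(random_plan(rng), rng)
        st.structure_id = f"corpus{i:04d}"
        corpus.entries.append((st, asn))

    db = build_loop_db(corpus.entries, min_len=min_len, max_len=max_len)
    corpus.db = db
    bundle = fit_bundle(db, [s for s, _ in corpus.entries], winsor_level=winsor_level)
    corpus.bundle = bundle

    from .bundle import train_pair_potential

    train_pair_potential(
        corpus.entries, db, bundle, bin_spec=bin_spec or BinSpec(),
        n_decoys=n_decoys, seed=seed,
    )
    spec = bin_spec or BinSpec()
    bundle.metadata.update(
        n_structures=n_structures, seed=seed, n_decoys=n_decoys,
        bin_spec={"r_lo": spec.r_lo, "r_hi": spec.r_hi, "w": spec.w},
    )
    return corpus
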