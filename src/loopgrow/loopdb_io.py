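"""Structure I/O and loop-database construction.

Reads PDB coordinate files (via gemmi), identifies loop regions from supplied
secondary-structure assignments, and walks each loop in growth order to
collect the raw material every empirical model is fitted from: anchor-distance
pairs per residue separation, residue-typed (phi, psi) tables, and side-chain
chi tables.

Secondary structure is consumed, never computed: a 3-column text file
(chain, author residue number, label in {H, E, C}) or a pre-parsed mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import chemistry
from .empirical_models import ChiTable, DihedralTable, DistancePairSet
from .geometry import GeometryError, measure_dihedral

WATER_NAMES = {"HOH", "WAT", "DOD"}
BACKBONE_NAMES = ("N", "CA", "C", "O")


class ParseError(ValueError):
    pass


@dataclass
class Residue:
    name: str  # 3-letter type
    seqnum: int  # author numbering
    icode: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def backbone_complete(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_NAMES)

    def coord(self, atom: str) -> np.ndarray:
        return self.atoms[atom]

    def heavy_atoms(self) -> list[tuple[str, np.ndarray]]:
        return list(self.atoms.items())

    def center(self) -> np.ndarray:
        return np.mean(list(self.atoms.values()), axis=0)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    hetero: list[tuple[str, str, np.ndarray]] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.structure_id}")

    def copy(self) -> "Structure":
        return Structure(
            self.structure_id,
            [
                Chain(c.chain_id, [Residue(r.name, r.seqnum, r.icode, {k: v.copy() for k, v in r.atoms.items()}) for r in c.residues])
                for c in self.chains
            ],
            list(self.hetero),
        )


@dataclass
class LoopRegion:
    """Half-open residue index range [start, end] (inclusive, 0-based per chain)."""

    chain_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_pdb(path: str | Path) -> Structure:
    """Parse ATOM/HETATM records; keeps the highest-occupancy altloc (ties go
    to 'A'), drops hydrogens and waters; other heteroatoms are kept aside in
    ``Structure.hetero`` and excluded from modeling."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), merge_chain_parts=True)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        return Structure(path.stem)
    model = st[0]
    out = Structure(path.stem)
    for ch in model:
        chain = Chain(ch.name)
        for res in ch:
            if res.name in WATER_NAMES:
                continue
            if res.het_flag == "H" and res.name not in chemistry.AMINO_ACIDS:
                for at in res:
                    if at.element.name != "H":
                        out.hetero.append((res.name, at.name, np.array([at.pos.x, at.pos.y, at.pos.z])))
                continue
            r = Residue(res.name, res.seqid.num, res.seqid.icode.strip())
            best: dict[str, tuple[float, str, np.ndarray]] = {}
            for at in res:
                if at.element.name == "H" or at.element.name == "D":
                    continue
                pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                alt = at.altloc or ""
                cur = best.get(at.name)
                cand = (at.occ, "A" if alt in ("", "A") else alt, pos)
                if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                    best[at.name] = cand
            for name, (_, _, pos) in best.items():
                r.atoms[name] = pos
            if r.atoms:
                chain.residues.append(r)
        if chain.residues:
            out.chains.append(chain)
    return out


def write_pdb(
    structure: Structure,
    path: str | Path,
    *,
    loop_tag: tuple[str, int, int] | None = None,
    bfactors: dict[tuple[str, int, str], float] | None = None,
) -> None:
    """Write fixed-column PDB coordinate records.

    ``loop_tag=(chain, start_seqnum, end_seqnum)`` adds a REMARK line marking
    the loop. ``bfactors`` maps (chain, seqnum, atom_name) to a value carried
    in the B-factor column (per-atom energies, typically).
    """
    lines: list[str] = []
    if loop_tag is not None:
        lines.append(f"REMARK 999 LOOP {loop_tag[0]} {loop_tag[1]} {loop_tag[2]}")
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for name in _ordered_atom_names(res):
                x, y, z = res.atoms[name]
                for v in (x, y, z):
                    if not (-999.999 <= v <= 9999.999):
                        raise ValueError(f"coordinate {v} overflows PDB 8.3 field")
                b = 0.0
                if bfactors:
                    b = bfactors.get((chain.chain_id, res.seqnum, name), 0.0)
                el = name[0]
                aname = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {aname:<4s}{'':1s}{res.name:<3s} {chain.chain_id:1s}"
                    f"{res.seqnum:4d}{res.icode or '':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          {el:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:<3s} {chain.chain_id}" if chain.residues else "TER")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _ordered_atom_names(res: Residue) -> list[str]:
    order = list(BACKBONE_NAMES)
    rest = sorted(n for n in res.atoms if n not in order)
    return [n for n in order if n in res.atoms] + rest


def read_assignment(path: str | Path) -> dict[str, dict[int, str]]:
    """Parse a 3-column secondary-structure file: chain, resnum, label."""
    out: dict[str, dict[int, str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3 or parts[2] not in "HEC" or len(parts[2]) != 1:
            raise ParseError(f"{path}:{ln}: expected 'chain resnum H|E|C', got {line!r}")
        out.setdefault(parts[0], {})[int(parts[1])] = parts[2]
    return out


def identify_loops(
    structure: Structure,
    assignment: dict[str, dict[int, str]],
    min_len: int = 4,
    max_len: int = 30,
    short_element_threshold: int = 4,
) -> list[LoopRegion]:
    """Find loop regions: maximal coil runs, where helix/strand runs not
    exceeding ``short_element_threshold`` residues are folded into the
    surrounding coil. Regions must satisfy the length window and have a
    complete backbone on every residue."""
    regions: list[LoopRegion] = []
    for chain in structure.chains:
        labels = []
        amap = assignment.get(chain.chain_id, {})
        for res in chain.residues:
            lab = amap.get(res.seqnum)
            if lab is None:
                raise ValueError(
                    f"assignment does not cover {chain.chain_id}/{res.seqnum}"
                )
            labels.append(lab)
        labels = _merge_short_elements(labels, short_element_threshold)
        i = 0
        n = len(labels)
        while i < n:
            if labels[i] != "C":
                i += 1
                continue
            j = i
            while j + 1 < n and labels[j + 1] == "C":
                j += 1
            length = j - i + 1
            if min_len <= length <= max_len and all(
                chain.residues[t].backbone_complete for t in range(i, j + 1)
            ):
                regions.append(LoopRegion(chain.chain_id, i, j))
            i = j + 1
    return regions


def _merge_short_elements(labels: list[str], threshold: int) -> list[str]:
    out = list(labels)
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == "C":
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        if j - i + 1 <= threshold:
            for t in range(i, j + 1):
                out[t] = "C"
        i = j + 1
    return out


@dataclass
class LoopRecord:
    structure_id: str
    chain_id: str
    start: int  # chain-internal index of first loop residue
    end: int  # inclusive
    sequence: list[str] = field(default_factory=list)
    phi: list[float] = field(default_factory=list)
    psi: list[float] = field(default_factory=list)
    omega: list[float] = field(default_factory=list)
    chi: list[list[float]] = field(default_factory=list)
    c_pairs: list[tuple[int, float, float]] = field(default_factory=list)  # (g, d_prev, d_new)
    n_pairs: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LoopDatabase:
    distance_pairs: dict[tuple[str, int], DistancePairSet] = field(default_factory=dict)
    dihedral_tables: dict[str, DihedralTable] = field(default_factory=dict)
    chi_tables: dict[str, ChiTable] = field(default_factory=dict)
    loops: list[LoopRecord] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def max_g(self) -> int:
        gs = [g for (_, g) in self.distance_pairs]
        return max(gs) if gs else 0


def anchor_atom(chain: Chain, region: LoopRegion) -> np.ndarray:
    """The fixed C-terminal anchor atom: N of the residue after the loop."""
    return chain.residues[region.end + 1].coord("N")


def walk_loop(
    structure: Structure, region: LoopRegion
) -> LoopRecord | None:
    """Record growth-order geometry for one interior loop.

    Returns None (with the reason implied by the contract) when the loop
    touches a terminus or a needed backbone atom is missing.
    """
    chain = structure.chain(region.chain_id)
    s, e = region.start, region.end
    if s < 1 or e + 1 >= len(chain.residues):
        return None
    prev_res = chain.residues[s - 1]
    next_res = chain.residues[e + 1]
    if not (prev_res.backbone_complete and next_res.backbone_complete):
        return None
    if not all(chain.residues[i].backbone_complete for i in range(s, e + 1)):
        return None

    anchor = next_res.coord("N")
    rec = LoopRecord(structure.structure_id, region.chain_id, s, e)
    residues = chain.residues

    def d(i: int, atom: str) -> float:
        return float(np.linalg.norm(residues[i].coord(atom) - anchor))

    # initial half-step: N of residue s guided from C of the N-side anchor
    g0 = e - s + 1
    rec.n_pairs.append((g0, d(s - 1, "C"), d(s, "N")))
    for j in range(s, e + 1):
        g = e - j + 1
        rec.c_pairs.append((g, d(j, "CA"), d(j, "C")))
        if j < e:
            rec.n_pairs.append((g - 1, d(j, "C"), d(j + 1, "N")))

    try:
        for j in range(s, e + 1):
            r = residues[j]
            nxt_n = residues[j + 1].coord("N") if j < e else anchor
            phi = measure_dihedral(residues[j - 1].coord("C"), r.coord("N"), r.coord("CA"), r.coord("C"))
            psi = measure_dihedral(r.coord("N"), r.coord("CA"), r.coord("C"), nxt_n)
            nxt_ca = residues[j + 1].coord("CA") if j < e else next_res.coord("CA")
            omega = measure_dihedral(r.coord("CA"), r.coord("C"), nxt_n, nxt_ca)
            rec.sequence.append(r.name)
            rec.phi.append(phi)
            rec.psi.append(psi)
            rec.omega.append(omega)
            rec.chi.append(_measure_chi(r))
    except (GeometryError, KeyError):
        return None
    return rec


def _measure_chi(res: Residue) -> list[float]:
    chi = []
    for quad in chemistry.chi_definitions(res.name):
        try:
            chi.append(measure_dihedral(*(res.coord(a) for a in quad)))
        except (KeyError, GeometryError):
            break
    return chi


def build_loop_db(
    entries: list[tuple[Structure, dict[str, dict[int, str]]]],
    min_len: int = 4,
    max_len: int = 30,
    short_element_threshold: int = 4,
    exclude_ids: set[str] | None = None,
) -> LoopDatabase:
    """Walk every identified loop of every structure and accumulate the
    distance pairs, dihedral tables and chi tables. Deterministic in input
    order; a manifest records per-structure loop counts and skip reasons."""
    if not entries:
        raise ValueError("need at least one structure")
    exclude_ids = exclude_ids or set()
    db = LoopDatabase()
    pair_store: dict[tuple[str, int], list] = {}
    manifest: dict = {"structures": [], "options": {
        "min_len": min_len, "max_len": max_len,
        "short_element_threshold": short_element_threshold,
    }}
    for structure, assignment in entries:
        if structure.structure_id in exclude_ids:
            manifest["structures"].append(
                {"id": structure.structure_id, "loops": 0, "excluded": True}
            )
            continue
        regions = identify_loops(
            structure, assignment, min_len, max_len, short_element_threshold
        )
        kept = 0
        skipped = 0
        for region in regions:
            rec = walk_loop(structure, region)
            if rec is None:
                skipped += 1
                continue
            kept += 1
            db.loops.append(rec)
            for model, pairs in (("C", rec.c_pairs), ("N", rec.n_pairs)):
                for g, dp, dn in pairs:
                    if g >= 1 and dp > 0 and dn > 0:
                        pair_store.setdefault((model, g), []).append((dp, dn))
            for res3, phi, psi, chis in zip(rec.sequence, rec.phi, rec.psi, rec.chi):
                tab = db.dihedral_tables.setdefault(res3, DihedralTable(res3))
                tab.add(phi, psi)
                nchi = chemistry.n_chi(res3)
                if nchi and len(chis) == nchi:
                    ct = db.chi_tables.setdefault(res3, ChiTable(res3, nchi))
                    ct.add(chis)
        manifest["structures"].append(
            {"id": structure.structure_id, "loops": kept, "skipped": skipped}
        )
    for (model, g), pairs in sorted(pair_store.items()):
        db.distance_pairs[(model, g)] = DistancePairSet(g, np.asarray(pairs))
    db.manifest = manifest
    return db


def save_manifest(db: LoopDatabase, path: str | Path) -> None:
    Path(path).write_text(json.dumps(db.manifest, indent=1))
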