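"""Loop-specific atom-pair distance-dependent statistical potential.

Heavy atoms are grouped into 20 types: the 4 backbone atoms (N, Ca, C, O)
plus 16 side-chain classes (6 carbon, 6 nitrogen, 3 oxygen, 1 sulfur).
Pair distances are binned (one sub-contact bin below ``r_lo``, then uniform
bins of width ``w`` up to ``r_hi``; beyond ``r_hi`` no interaction), and the
energy of a (type_i, type_j, bin) cell is the negative log ratio of the
observed pair probability in database loops to the expected probability in
geometry-only decoy loops:

    E(i, j, r) = -ln[ (n_obs(i,j,r)/N_obs) / (n_exp(i,j,r)/N_exp) ]

Cells never observed (or never expected) get a finite repulsive cap; the
sub-contact bin always carries the clash constant so sterically impossible
placements are strongly, but finitely, penalized - they must remain drawable
with vanishing Boltzmann weight, not crash the sampler.

Exclusions: atom pairs within one residue, and 1-2/1-3 pairs across the
peptide bond, are excluded from every count and every energy; they are fixed
by covalent geometry and would only add a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import chemistry

DEFAULT_CAP = 3.0
DEFAULT_CLASH = 10.0


class TypingError(KeyError):
    pass


@lru_cache(maxsize=1)
def atom_type_scheme() -> "AtomTypeScheme":
    return AtomTypeScheme()


class AtomTypeScheme:
    """Mapping (residue_type, atom_name) -> integer type id (0..19)."""

    def __init__(self) -> None:
        table = chemistry.atom_type_table()
        self.backbone = dict(table["backbone"])
        classes = table["side_chain_classes"]
        self.type_names: list[str] = ["bbN", "bbCA", "bbC", "bbO"]
        for group in ("carbon", "nitrogen", "oxygen", "sulfur"):
            self.type_names.extend(classes[group])
        self.index = {n: i for i, n in enumerate(self.type_names)}
        self.side_chain = table["side_chain"]

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def assign(self, residue_type: str, atom_name: str) -> int:
        if atom_name in self.backbone:
            return self.index[self.backbone[atom_name]]
        try:
            return self.index[self.side_chain[residue_type][atom_name]]
        except KeyError as exc:
            raise TypingError(
                f"no atom type for {residue_type}/{atom_name}"
            ) from exc


def assign_atom_type(residue_type: str, atom_name: str) -> int:
    return atom_type_scheme().assign(residue_type, atom_name)


@dataclass(frozen=True)
class BinSpec:
    """Distance binning: [0, r_lo) is the sub-contact bin 0; then uniform
    width-``w`` bins up to ``r_hi``; >= r_hi means no interaction."""

    r_lo: float = 2.0
    r_hi: float = 8.0
    w: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.r_lo < self.r_hi) or self.w <= 0:
            raise ValueError("need 0 < r_lo < r_hi and w > 0")

    @property
    def n_bins(self) -> int:
        return 1 + int(np.ceil((self.r_hi - self.r_lo) / self.w - 1e-12))

    def bin_of(self, distance: float) -> int | None:
        """Bin index for one distance; None beyond r_hi."""
        if distance < 0:
            raise ValueError("distance must be >= 0")
        if distance >= self.r_hi:
            return None
        if distance < self.r_lo:
            return 0
        return 1 + int((distance - self.r_lo) / self.w)

    def bins_of(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized binning: (mask of interacting pairs, bin indices)."""
        d = np.asarray(d, dtype=float)
        mask = d < self.r_hi
        idx = np.where(
            d < self.r_lo, 0, 1 + ((d - self.r_lo) / self.w).astype(int)
        )
        return mask, np.clip(idx, 0, self.n_bins - 1)


@dataclass
class AtomSet:
    """Flat arrays describing a set of heavy atoms for pair computations."""

    pos: np.ndarray  # (n, 3)
    types: np.ndarray  # (n,) int
    res_key: np.ndarray  # (n,) int: chain_index * 100000 + residue_index
    name_code: np.ndarray  # (n,) int: N=0 CA=1 C=2 O=3 other=4

    def __len__(self) -> int:
        return len(self.pos)

    @staticmethod
    def empty() -> "AtomSet":
        return AtomSet(
            np.zeros((0, 3)), np.zeros(0, int), np.zeros(0, int), np.zeros(0, int)
        )

    @staticmethod
    def concat(sets: list["AtomSet"]) -> "AtomSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return AtomSet.empty()
        return AtomSet(
            np.concatenate([s.pos for s in sets]),
            np.concatenate([s.types for s in sets]),
            np.concatenate([s.res_key for s in sets]),
            np.concatenate([s.name_code for s in sets]),
        )


_NAME_CODES = {"N": 0, "CA": 1, "C": 2, "O": 3}


def atoms_from_residues(
    residues, chain_index: int, res_indices, *, skip_unknown: bool = True
) -> AtomSet:
    """Build an :class:`AtomSet` from Residue objects (loopdb_io containers).

    ``res_indices`` gives each residue's chain-internal index (for the
    exclusion rules). Unknown atom names are skipped with the scheme's
    blessing when ``skip_unknown``; otherwise they raise."""
    scheme = atom_type_scheme()
    pos, types, keys, codes = [], [], [], []
    for res, ridx in zip(residues, res_indices):
        for name, xyz in res.atoms.items():
            try:
                t = scheme.assign(res.name, name)
            except TypingError:
                if skip_unknown:
                    continue
                raise
            pos.append(xyz)
            types.append(t)
            keys.append(chain_index * 100000 + ridx)
            codes.append(_NAME_CODES.get(name, 4))
    if not pos:
        return AtomSet.empty()
    return AtomSet(
        np.asarray(pos, dtype=float),
        np.asarray(types, dtype=int),
        np.asarray(keys, dtype=int),
        np.asarray(codes, dtype=int),
    )


def _excluded(a: AtomSet, b: AtomSet) -> np.ndarray:
    """Boolean (len(a), len(b)) matrix of excluded pairs: same residue, or
    1-2/1-3 neighbors across the peptide bond (C-N, CA-N, O-N, C-CA)."""
    ka = a.res_key[:, None]
    kb = b.res_key[None, :]
    same = ka == kb
    # adjacency: residue of a immediately before residue of b, or vice versa
    fwd = kb - ka == 1  # a's residue precedes b's
    rev = ka - kb == 1
    ca = a.name_code[:, None]
    cb = b.name_code[None, :]
    # preceding residue contributes C (2), CA (1), O (3); following contributes N (0), CA (1)
    fwd_excl = fwd & (
        ((ca == 2) & (cb == 0))
        | ((ca == 1) & (cb == 0))
        | ((ca == 3) & (cb == 0))
        | ((ca == 2) & (cb == 1))
    )
    rev_excl = rev & (
        ((cb == 2) & (ca == 0))
        | ((cb == 1) & (ca == 0))
        | ((cb == 3) & (ca == 0))
        | ((cb == 2) & (ca == 1))
    )
    return same | fwd_excl | rev_excl


def _pair_bins(
    a: AtomSet, b: AtomSet, spec: BinSpec, *, same_set: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interacting (i, j, bin) triples between two atom sets (unordered when
    ``same_set``), with exclusions applied."""
    if len(a) == 0 or len(b) == 0:
        z = np.zeros(0, int)
        return z, z, z
    d = np.linalg.norm(a.pos[:, None, :] - b.pos[None, :, :], axis=-1)
    mask, bins = spec.bins_of(d)
    mask &= ~_excluded(a, b)
    if same_set:
        mask &= np.triu(np.ones_like(mask, dtype=bool), k=1)
    ii, jj = np.nonzero(mask)
    return ii, jj, bins[ii, jj]


@dataclass
class PairCounts:
    """Symmetric (type, type, bin) count tensor."""

    spec: BinSpec
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = atom_type_scheme().n_types
        if self.counts is None:
            self.counts = np.zeros((n, n, self.spec.n_bins))
        self.counts = np.asarray(self.counts, dtype=float)

    def accumulate(self, a: AtomSet, b: AtomSet, *, same_set: bool, weight: float = 1.0) -> None:
        ii, jj, bb = _pair_bins(a, b, self.spec, same_set=same_set)
        ta, tb = a.types[ii], b.types[jj]
        np.add.at(self.counts, (ta, tb, bb), weight)
        off = ta != tb
        np.add.at(self.counts, (tb[off], ta[off], bb[off]), weight)

    @property
    def total(self) -> float:
        """Total pair count N (each unordered pair once, regardless of type)."""
        n = self.counts.shape[0]
        diag = self.counts[np.arange(n), np.arange(n), :].sum()
        return float((self.counts.sum() + diag) / 2.0)


def loop_atom_set(structure, chain_id: str, start: int, end: int) -> AtomSet:
    chain_index = [c.chain_id for c in structure.chains].index(chain_id)
    chain = structure.chain(chain_id)
    return atoms_from_residues(
        chain.residues[start : end + 1], chain_index, range(start, end + 1)
    )


def environment_atom_set(
    structure, chain_id: str, start: int, end: int, keep=None
) -> AtomSet:
    """All fixed (non-loop) protein atoms, optionally filtered by ``keep``,
    a predicate on (chain_id, residue_index, Residue)."""
    sets = []
    for ci, chain in enumerate(structure.chains):
        for ri, res in enumerate(chain.residues):
            if chain.chain_id == chain_id and start <= ri <= end:
                continue
            if keep is not None and not keep(chain.chain_id, ri, res):
                continue
            sets.append(atoms_from_residues([res], ci, [ri]))
    return AtomSet.concat(sets)


def count_observed(
    loop_entries: list[tuple[AtomSet, AtomSet]], spec: BinSpec
) -> PairCounts:
    """Observed counts over (loop atoms, environment atoms) pairs for every
    database loop: loop-environment pairs plus intra-loop pairs counted once."""
    pc = PairCounts(spec)
    for loop_atoms, env_atoms in loop_entries:
        pc.accumulate(loop_atoms, env_atoms, same_set=False)
        pc.accumulate(loop_atoms, loop_atoms, same_set=True)
    return pc


def count_expected(
    decoy_entries: list[list[tuple[AtomSet, AtomSet]]], spec: BinSpec
) -> PairCounts:
    """Expected counts: per loop, the mean over its decoys; summed over loops.
    Loops with no decoys are skipped."""
    pc = PairCounts(spec)
    for decoys in decoy_entries:
        if not decoys:
            continue
        w = 1.0 / len(decoys)
        for loop_atoms, env_atoms in decoys:
            pc.accumulate(loop_atoms, env_atoms, same_set=False, weight=w)
            pc.accumulate(loop_atoms, loop_atoms, same_set=True, weight=w)
    return pc


@dataclass
class PairPotential:
    spec: BinSpec
    energy: np.ndarray  # (n_types, n_types, n_bins)
    clash_energy: float = DEFAULT_CLASH
    cap: float = DEFAULT_CAP
    n_obs: np.ndarray | None = None
    n_exp: np.ndarray | None = None

    def lookup(self, types_a, types_b, bins) -> np.ndarray:
        return self.energy[types_a, types_b, bins]


def build_potential(
    n_obs: PairCounts,
    n_exp: PairCounts,
    cap: float = DEFAULT_CAP,
    clash_energy: float = DEFAULT_CLASH,
) -> PairPotential:
    if n_obs.spec != n_exp.spec:
        raise ValueError("count tensors use different bin specs")
    tot_obs, tot_exp = n_obs.total, n_exp.total
    if tot_obs <= 0 or tot_exp <= 0:
        raise ValueError("cannot build potential from all-zero counts")
    p_obs = n_obs.counts / tot_obs
    p_exp = n_exp.counts / tot_exp
    with np.errstate(divide="ignore", invalid="ignore"):
        e = -np.log(p_obs / p_exp)
    e[(n_obs.counts == 0) | (n_exp.counts == 0)] = cap
    e[:, :, 0] = clash_energy  # sub-contact bin: always the clash constant
    e = 0.5 * (e + e.transpose(1, 0, 2))  # enforce exact symmetry
    return PairPotential(
        spec=n_obs.spec, energy=e, clash_energy=clash_energy, cap=cap,
        n_obs=n_obs.counts.copy(), n_exp=n_exp.counts.copy(),
    )


def pair_energy(
    potential: PairPotential, a: AtomSet, b: AtomSet, *, same_set: bool
) -> float:
    ii, jj, bb = _pair_bins(a, b, potential.spec, same_set=same_set)
    if len(ii) == 0:
        return 0.0
    return float(potential.lookup(a.types[ii], b.types[jj], bb).sum())


def score_loop(loop_atoms: AtomSet, env_atoms: AtomSet, potential: PairPotential) -> float:
    """Total energy of a loop conformation: every unordered atom pair with at
    least one loop atom within interaction range."""
    return pair_energy(potential, loop_atoms, env_atoms, same_set=False) + pair_energy(
        potential, loop_atoms, loop_atoms, same_set=True
    )


def fragment_energy(
    new_atoms: AtomSet, context_atoms: AtomSet, potential: PairPotential
) -> float:
    """Energy of newly placed atoms against the fixed protein plus previously
    grown loop atoms (``context_atoms``), plus intra-fragment pairs; summing
    fragment energies over all growth steps telescopes exactly to
    :func:`score_loop` of the finished loop."""
    return pair_energy(potential, new_atoms, context_atoms, same_set=False) + pair_energy(
        potential, new_atoms, new_atoms, same_set=True
    )


def export_tsv(potential: PairPotential, path) -> None:
    """Human-readable table: type_i type_j bin_lo bin_hi n_obs n_exp E."""
    scheme = atom_type_scheme()
    spec = potential.spec
    lines = ["type_i\ttype_j\tbin_lo\tbin_hi\tn_obs\tn_exp\tE"]
    edges = [0.0, spec.r_lo] + [
        spec.r_lo + k * spec.w for k in range(1, spec.n_bins)
    ]
    edges.append(spec.r_hi)
    for i in range(scheme.n_types):
        for j in range(i, scheme.n_types):
            for b in range(spec.n_bins):
                no = potential.n_obs[i, j, b] if potential.n_obs is not None else float("nan")
                ne = potential.n_exp[i, j, b] if potential.n_exp is not None else float("nan")
                lines.append(
                    f"{scheme.type_names[i]}\t{scheme.type_names[j]}\t"
                    f"{edges[b]:.2f}\t{edges[b + 1]:.2f}\t{no:g}\t{ne:g}\t"
                    f"{potential.energy[i, j, b]:.6f}"
                )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
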