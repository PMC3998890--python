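"""Redcell: REsidue-residue Distance Cutoff and ELLipsoid criterion.

Bounds the set of atoms that can ever interact with a sampled loop so the
energy cost per conformation is independent of protein size. Two tests:

* residue-level cutoff: residue j is kept if its geometric center lies within
  r_i + r_j + c of a loop anchor, where the effective radius r of a residue
  type is the largest center-to-heavy-atom distance observed in the loop
  database;
* ellipsoid: the loop's two anchor atoms are the foci; any point a sampled
  loop atom can reach satisfies |P - f1| + |P - f2| < L_total (the sum of the
  loop's backbone bond lengths). The ellipsoid is enlarged by the maximum
  side-chain length s_max plus the interaction cutoff d_cut, and atoms outside
  it are permanently excluded from energy evaluation.

With c and d_cut at least the potential's interaction range the filtered
energies are exactly the unfiltered ones. The same ellipsoid prunes growth:
a trial atom placed outside it can never close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .loopdb_io import LoopDatabase, Structure

DEFAULT_C = 8.0


@dataclass
class ResidueRadiusTable:
    """Effective radius per residue type (Å): max distance from the residue's
    geometric center to any of its heavy atoms."""

    radii: dict[str, float] = field(default_factory=dict)

    def radius(self, residue_type: str) -> float:
        try:
            return self.radii[residue_type]
        except KeyError as exc:
            raise KeyError(f"no effective radius for {residue_type!r}") from exc


def radius_table_from_structures(structures: list[Structure]) -> ResidueRadiusTable:
    """Compute effective radii from observed residues (loop database corpus)."""
    best: dict[str, float] = {}
    for st in structures:
        for chain in st.chains:
            for res in chain.residues:
                if len(res.atoms) < 2:
                    continue
                center = res.center()
                r = max(float(np.linalg.norm(p - center)) for p in res.atoms.values())
                best[res.name] = max(best.get(res.name, 0.0), r)
    # clamp into the physically sensible band
    return ResidueRadiusTable({k: float(np.clip(v, 1.01, 7.99)) for k, v in best.items()})


def residue_cutoff(
    type_i: str, type_j: str, table: ResidueRadiusTable, c: float = DEFAULT_C
) -> float:
    """Residue-dependent center-to-center cutoff r_i + r_j + c (symmetric)."""
    return table.radius(type_i) + table.radius(type_j) + c


class InfeasibleAnchorsError(ValueError):
    pass


@dataclass
class LoopEllipsoid:
    """Prolate ellipsoid with the two loop anchors as foci.

    Membership is tested directly against the defining sum-of-distances
    inequality |P-f1| + |P-f2| < threshold (strict)."""

    f1: np.ndarray
    f2: np.ndarray
    l_total: float
    enlargement: float

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        if np.linalg.norm(self.f1 - self.f2) >= self.threshold:
            raise InfeasibleAnchorsError(
                "anchor separation exceeds the loop's maximum reach"
            )

    @property
    def threshold(self) -> float:
        return self.l_total + self.enlargement

    @property
    def semi_major(self) -> float:
        return self.threshold / 2.0

    @property
    def semi_minor(self) -> float:
        c2 = (np.linalg.norm(self.f2 - self.f1) / 2.0) ** 2
        return float(np.sqrt(self.semi_major**2 - c2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        s = np.linalg.norm(p - self.f1, axis=1) + np.linalg.norm(p - self.f2, axis=1)
        out = s < self.threshold
        return out if np.asarray(points).ndim == 2 else bool(out[0])


def backbone_span(loop_residue_types: list[str]) -> float:
    """Sum of backbone bond lengths along the loop path from the N-side
    anchor's C to the C-side anchor's N: (C-N, N-CA, CA-C) per residue plus
    the final C-N junction bond."""
    t = chemistry.bond_table()["bonds"]
    per_res = t["C-N"] + t["N-CA"] + t["CA-C"]
    return per_res * len(loop_residue_types) + t["C-N"]


def build_ellipsoid(
    f1: np.ndarray,
    f2: np.ndarray,
    loop_residue_types: list[str],
    s_max: float | None = None,
    d_cut: float = 8.0,
) -> LoopEllipsoid:
    """Ellipsoid for a loop with the given residue types between anchors
    ``f1`` (N-side anchor C atom) and ``f2`` (C-side anchor N atom)."""
    if len(loop_residue_types) < 1:
        raise ValueError("loop must have at least one residue")
    if s_max is None:
        s_max = chemistry.max_sidechain_length()
    return LoopEllipsoid(
        f1=f1,
        f2=f2,
        l_total=backbone_span(loop_residue_types),
        enlargement=s_max + d_cut,
    )


def prune_growth(point: np.ndarray, ellipsoid: LoopEllipsoid) -> bool:
    """True = keep; False = abort the growth attempt (atom left the ellipsoid,
    boundary counts as outside)."""
    return bool(ellipsoid.contains(np.asarray(point)))


def environment_residue_filter(
    structure: Structure,
    chain_id: str,
    start: int,
    end: int,
    ellipsoid: LoopEllipsoid,
    table: ResidueRadiusTable,
    c: float = DEFAULT_C,
    loop_residue_types: list[str] | None = None,
):
    """Predicate selecting fixed residues that can interact with the loop.

    A residue is retained when its center passes the residue-cutoff test
    against either anchor (anchors bound the not-yet-sampled loop residue
    centers) or any of its atoms lies inside the enlarged ellipsoid."""
    if loop_residue_types is None:
        loop_residue_types = [
            r.name for r in structure.chain(chain_id).residues[start : end + 1]
        ]
    r_loop = max((table.radii.get(t, 4.0) for t in loop_residue_types), default=4.0)

    def keep(cid: str, ridx: int, res) -> bool:
        center = res.center()
        for anchor in (ellipsoid.f1, ellipsoid.f2):
            cut = table.radii.get(res.name, 4.0) + r_loop + c
            if np.linalg.norm(center - anchor) <= cut:
                return True
        pts = np.asarray(list(res.atoms.values()))
        return bool(np.any(ellipsoid.contains(pts)))

    return keep
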