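"""Fitted parameter bundle: everything the sampler needs at run time.

Bundles are fitted from a loop database (distance KDEs per separation and
placement model, dihedral and chi tables per residue type, the pair potential,
and the residue radius table) and serialized as a single JSON archive with a
metadata block recording the fit options and corpus fingerprint.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .empirical_models import (
    FitError,
    ChiTable,
    DEFAULT_WINSOR_LEVEL,
    DihedralTable,
    DistancePairSet,
    Kde2D,
    fit_kde2d,
)
from .loopdb_io import LoopDatabase, Structure
from .potential import BinSpec, PairPotential
from .redcell import ResidueRadiusTable, radius_table_from_structures


@dataclass
class ModelBundle:
    kdes: dict[tuple[str, int], Kde2D]
    dihedral_tables: dict[str, DihedralTable]
    chi_tables: dict[str, ChiTable]
    potential: PairPotential | None
    radius_table: ResidueRadiusTable
    metadata: dict = field(default_factory=dict)

    def max_g(self, model: str) -> int:
        gs = [g for (m, g) in self.kdes if m == model]
        if not gs:
            raise KeyError(f"no fitted distance models of kind {model!r}")
        return max(gs)

    def kde_for(self, model: str, g: int) -> Kde2D:
        """KDE at the nearest fitted separation to ``g`` (larger separations
        reuse the largest-g model; unfittable separations fall back to the
        closest neighbor)."""
        gs = sorted(gg for (m, gg) in self.kdes if m == model)
        if not gs:
            raise KeyError(f"no fitted distance models of kind {model!r}")
        nearest = min(gs, key=lambda gg: (abs(gg - g), gg))
        return self.kdes[(model, nearest)]


def fit_distance_models(
    db: LoopDatabase, winsor_level: float = DEFAULT_WINSOR_LEVEL
) -> dict[tuple[str, int], Kde2D]:
    kdes = {}
    for key, pairset in sorted(db.distance_pairs.items()):
        if len(pairset.pairs) < 10:
            continue
        try:
            kdes[key] = fit_kde2d(pairset, winsor_level=winsor_level)
        except FitError:
            # degenerate separations (e.g. the last C placement, whose anchor
            # distance is covalently fixed) are never consumed by the sampler
            continue
    return kdes


def fit_bundle(
    db: LoopDatabase,
    structures: list[Structure],
    potential: PairPotential | None = None,
    winsor_level: float = DEFAULT_WINSOR_LEVEL,
) -> ModelBundle:
    """Assemble a bundle from a built database (the potential, which needs
    decoys, may be attached separately)."""
    fingerprint = hashlib.sha256(
        json.dumps(db.manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    return ModelBundle(
        kdes=fit_distance_models(db, winsor_level),
        dihedral_tables=dict(db.dihedral_tables),
        chi_tables=dict(db.chi_tables),
        potential=potential,
        radius_table=radius_table_from_structures(structures),
        metadata={
            "version": __version__,
            "winsor_level": winsor_level,
            "corpus_fingerprint": fingerprint,
            "n_loops": len(db.loops),
        },
    )


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    out = {
        "metadata": bundle.metadata,
        "kdes": {
            f"{m}:{g}": {
                "x_nodes": k.x_nodes.tolist(),
                "y_nodes": k.y_nodes.tolist(),
                "grid": k.grid.tolist(),
                "bandwidth": np.asarray(k.bandwidth).tolist(),
                "n_data": k.n_data,
            }
            for (m, g), k in bundle.kdes.items()
        },
        "dihedral_tables": {
            r: {"bin_width": t.bin_width, "counts": t.counts.tolist(),
                "pseudocount_fraction": t.pseudocount_fraction}
            for r, t in bundle.dihedral_tables.items()
        },
        "chi_tables": {
            r: {
                "n_chi": t.n_chi,
                "bin_width": t.bin_width,
                "bins": [
                    {"key": list(k), "count": v[0], "mean": np.asarray(v[1]).tolist()}
                    for k, v in sorted(t.bins.items())
                ],
            }
            for r, t in bundle.chi_tables.items()
        },
        "radius_table": bundle.radius_table.radii,
    }
    if bundle.potential is not None:
        p = bundle.potential
        out["potential"] = {
            "spec": {"r_lo": p.spec.r_lo, "r_hi": p.spec.r_hi, "w": p.spec.w},
            "energy": p.energy.tolist(),
            "clash_energy": p.clash_energy,
            "cap": p.cap,
        }
    Path(path).write_text(json.dumps(out))


def load_bundle(path: str | Path) -> ModelBundle:
    raw = json.loads(Path(path).read_text())
    kdes = {}
    for key, k in raw["kdes"].items():
        m, g = key.split(":")
        kdes[(m, int(g))] = Kde2D(
            x_nodes=np.asarray(k["x_nodes"]),
            y_nodes=np.asarray(k["y_nodes"]),
            grid=np.asarray(k["grid"]),
            bandwidth=np.asarray(k["bandwidth"]),
            n_data=k["n_data"],
        )
    dts = {
        r: DihedralTable(
            r, bin_width=t["bin_width"], counts=np.asarray(t["counts"]),
            pseudocount_fraction=t["pseudocount_fraction"],
        )
        for r, t in raw["dihedral_tables"].items()
    }
    cts = {}
    for r, t in raw["chi_tables"].items():
        ct = ChiTable(r, t["n_chi"], t["bin_width"])
        for b in t["bins"]:
            ct.bins[tuple(b["key"])] = [b["count"], np.asarray(b["mean"])]
        cts[r] = ct
    potential = None
    if "potential" in raw:
        p = raw["potential"]
        potential = PairPotential(
            spec=BinSpec(**p["spec"]),
            energy=np.asarray(p["energy"]),
            clash_energy=p["clash_energy"],
            cap=p["cap"],
        )
    return ModelBundle(
        kdes=kdes,
        dihedral_tables=dts,
        chi_tables=cts,
        potential=potential,
        radius_table=ResidueRadiusTable(dict(raw["radius_table"])),
        metadata=raw.get("metadata", {}),
    )


def train_pair_potential(
    entries: list[tuple[Structure, dict]],
    db: LoopDatabase,
    bundle: ModelBundle,
    bin_spec=None,
    n_decoys: int = 3,
    seed: int = 0,
) -> None:
    """Train the pair potential in place: observed counts from the database
    loops, expected counts from geometry-only decoys grown with a flat
    potential."""
    from .potential import (
        BinSpec,
        PairPotential,
        atom_type_scheme,
        atoms_from_residues,
        build_potential,
        count_expected,
        count_observed,
        environment_atom_set,
        loop_atom_set,
    )
    from .sampler import LoopSpec, SamplerConfig, SamplingFailure, build_side_chains, sample_loop

    spec = bin_spec or BinSpec()
    structs = {st.structure_id: st for st, _ in entries}
    observed_entries = []
    loop_refs = []
    for rec in db.loops:
        st = structs[rec.structure_id]
        observed_entries.append(
            (
                loop_atom_set(st, rec.chain_id, rec.start, rec.end),
                environment_atom_set(st, rec.chain_id, rec.start, rec.end),
            )
        )
        loop_refs.append((st, rec))
    n_obs = count_observed(observed_entries, spec)

    n = atom_type_scheme().n_types
    bundle.potential = PairPotential(spec=spec, energy=np.zeros((n, n, spec.n_bins)))
    decoy_cfg = SamplerConfig(m=1, k=1, max_restarts=30)
    decoy_rng = np.random.default_rng(seed + 1)
    decoy_entries = []
    for st, rec in loop_refs:
        lspec = LoopSpec(rec.chain_id, rec.start, rec.end)
        env = environment_atom_set(st, rec.chain_id, rec.start, rec.end)
        decoys = []
        for _ in range(n_decoys):
            r = np.random.default_rng(decoy_rng.integers(0, 2**31 - 1))
            try:
                conf = sample_loop(st, lspec, bundle, decoy_cfg, r)
                conf = build_side_chains(conf, st, bundle, decoy_cfg, r)
            except (SamplingFailure, ValueError):
                continue
            chain_index = [c.chain_id for c in st.chains].index(rec.chain_id)
            loop_atoms = atoms_from_residues(
                conf.residues, chain_index, range(rec.start, rec.end + 1)
            )
            decoys.append((loop_atoms, env))
        decoy_entries.append(decoys)
    n_exp = count_expected(decoy_entries, spec)
    bundle.potential = build_potential(n_obs, n_exp)
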