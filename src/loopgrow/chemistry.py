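"""Shared chemical reference data: backbone covalent geometry, side-chain
internal-coordinate templates, χ definitions, and van der Waals radii.

The tables ship as editable JSON under ``loopgrow/data``. The bond-geometry
table is a standard-value stand-in (the classic refined small-molecule values),
versioned with the package; every tolerance elsewhere references it.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .geometry import BondGeometry, Frame, place_atom

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


def _load_json(name: str) -> dict:
    with resources.files("loopgrow.data").joinpath(name).open() as f:
        return json.load(f)


@lru_cache(maxsize=1)
def bond_table() -> dict:
    return _load_json("bond_geometry.json")


@lru_cache(maxsize=1)
def sidechain_templates() -> dict:
    return _load_json("sidechain_templates.json")["residues"]


@lru_cache(maxsize=1)
def atom_type_table() -> dict:
    return _load_json("atom_types.json")


class BackboneGeometry:
    """Residue-aware accessors for backbone bond lengths/angles."""

    def __init__(self) -> None:
        t = bond_table()
        self.bonds = t["bonds"]
        self.angles = t["angles"]
        self.pro = t["proline"]
        self.gly = t["glycine"]
        self.omega_trans = t["omega_trans"]

    def angle_n_ca_c(self, restype: str) -> float:
        if restype == "PRO":
            return self.pro["N-CA-C"]
        if restype == "GLY":
            return self.gly["N-CA-C"]
        return self.angles["N-CA-C"]

    def angle_c_n_ca(self, restype: str) -> float:
        """Angle at N of ``restype`` (the residue following the peptide bond)."""
        if restype == "PRO":
            return self.pro["C-N-CA"]
        return self.angles["C-N-CA"]

    # placement geometries (the atom named is the one being placed)
    def geom_c(self, restype: str) -> BondGeometry:
        return BondGeometry(self.bonds["CA-C"], self.angle_n_ca_c(restype))

    def geom_n(self, next_restype: str = "ALA") -> BondGeometry:
        return BondGeometry(self.bonds["C-N"], self.angles["CA-C-N"])

    def geom_ca(self, restype: str) -> BondGeometry:
        return BondGeometry(self.bonds["N-CA"], self.angle_c_n_ca(restype))

    def geom_o(self) -> BondGeometry:
        return BondGeometry(self.bonds["C-O"], self.angles["CA-C-O"])


@lru_cache(maxsize=1)
def backbone_geometry() -> BackboneGeometry:
    return BackboneGeometry()


def chi_definitions(restype: str) -> list[list[str]]:
    """Atom-name quadruples defining each χ of ``restype`` (may be empty)."""
    return sidechain_templates().get(restype, {}).get("chi", [])


def canonical_chi(restype: str) -> list[float]:
    return list(sidechain_templates().get(restype, {}).get("canonical_chi", []))


def n_chi(restype: str) -> int:
    return len(chi_definitions(restype))


def sidechain_atom_names(restype: str) -> list[str]:
    tmpl = sidechain_templates().get(restype)
    if tmpl is None:
        raise KeyError(f"unknown residue type {restype!r}")
    return [rec["name"] for rec in tmpl["atoms"]]


def build_side_chain(
    restype: str, backbone: dict[str, np.ndarray], chi: list[float] | np.ndarray
) -> dict[str, np.ndarray]:
    """Construct side-chain heavy-atom coordinates from the template.

    ``backbone`` must contain N, CA, C. ``chi`` supplies the residue's χ
    dihedrals in degrees (length :func:`n_chi`); extra values are ignored.
    """
    tmpl = sidechain_templates().get(restype)
    if tmpl is None:
        raise KeyError(f"unknown residue type {restype!r}")
    chi = list(chi)
    if len(chi) < len(tmpl["chi"]):
        raise ValueError(
            f"{restype} needs {len(tmpl['chi'])} chi angles, got {len(chi)}"
        )
    pos: dict[str, np.ndarray] = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    out: dict[str, np.ndarray] = {}
    for rec in tmpl["atoms"]:
        a, b, c = (pos[n] for n in rec["frame"])
        spec = rec["dihedral"]
        if "chi" in spec:
            dihedral = chi[spec["chi"] - 1] + spec["offset"]
        else:
            dihedral = spec["fixed"]
        p = place_atom(Frame(a, b, c), BondGeometry(rec["bond"], rec["angle"]), dihedral)
        pos[rec["name"]] = p
        out[rec["name"]] = p
    return out


def vdw_radius(atom_name: str) -> float:
    """Van der Waals radius by leading element letter of a heavy-atom name."""
    radii = atom_type_table()["vdw_radii"]
    el = atom_name[0]
    if el not in radii:
        raise KeyError(f"no vdW radius for atom {atom_name!r}")
    return radii[el]


@lru_cache(maxsize=1)
def max_sidechain_length() -> float:
    """Maximum Cα-to-side-chain-atom reach over all residue types (Å).

    Computed from the shipped templates (arginine in practice); used to
    enlarge the loop ellipsoid so side chains cannot escape it.
    """
    geo = backbone_geometry()
    best = 0.0
    for res in AMINO_ACIDS:
        if n_chi(res) == 0 and res != "ALA":
            continue
        # ideal extended backbone stub
        n = np.array([0.0, 0.0, 0.0])
        ca = np.array([geo.bonds["N-CA"], 0.0, 0.0])
        c = place_atom(
            Frame(np.array([0.0, 1.0, 0.0]), n, ca), geo.geom_c(res), 120.0
        )
        chi = [180.0] * n_chi(res)  # extended chain = maximal reach
        atoms = build_side_chain(res, {"N": n, "CA": ca, "C": c}, chi)
        for p in atoms.values():
            best = max(best, float(np.linalg.norm(p - ca)))
    return best
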