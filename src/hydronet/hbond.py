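"""Geometric hydrogen-bond detection.

Detects hydrogen bonds among protein polar atoms, waters and (optionally)
ligand polar atoms using heavy-atom geometric criteria.  The detector is
designed to work on hydrogen-free coordinates, which is the norm for
membrane-protein crystal structures: a bond requires donor/acceptor role
compatibility, a heavy-atom distance window, and (when the donor is not a
water) an antecedent-donor-acceptor angle proxy that rejects geometries where
the putative acceptor sits behind the donor's covalent attachment.

Criteria are fully configurable so counts can be calibrated against models
scored with an explicit-solvation forcefield.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Residue, StructureModel

# Donor/acceptor roles of heavy atoms, per residue type.  Backbone N is a
# donor (except proline) and backbone O an acceptor for every amino acid;
# side-chain entries are listed explicitly.  Role "both" marks hydroxyls,
# water oxygen and histidine ring nitrogens (protonation unknown).
_BACKBONE_ROLES = {"N": "donor", "O": "acceptor", "OXT": "acceptor"}

_SIDECHAIN_ROLES: dict[str, dict[str, str]] = {
    "SER": {"OG": "both"},
    "THR": {"OG1": "both"},
    "TYR": {"OH": "both"},
    "CYS": {"SG": "both"},
    "ASN": {"OD1": "acceptor", "ND2": "donor"},
    "GLN": {"OE1": "acceptor", "NE2": "donor"},
    "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
    "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
    "HIS": {"ND1": "both", "NE2": "both"},
    "LYS": {"NZ": "donor"},
    "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
    "TRP": {"NE1": "donor"},
    "MET": {"SD": "acceptor"},
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Covalent antecedent of each polar heavy atom, used for the angle proxy.
_ANTECEDENT: dict[str, str] = {
    "N": "CA", "O": "C", "OXT": "C",
    "OG": "CB", "OG1": "CB", "OH": "CZ", "SG": "CB",
    "OD1": "CG", "OD2": "CG", "ND2": "CG",
    "OE1": "CD", "OE2": "CD", "NE2": "CD",
    "ND1": "CG",
    "NZ": "CE", "NE": "CD", "NH1": "CZ", "NH2": "CZ",
    "NE1": "CD1", "SD": "CG",
}
# HIS NE2 antecedent differs from GLN's.
_ANTECEDENT_BY_RES = {("HIS", "NE2"): "CD2", ("HIS", "ND1"): "CG"}

WATER_ATOM_ROLES = {"O": "both", "OW": "both"}


@dataclass(frozen=True)
class HBondCriteria:
    """Heavy-atom geometric criteria for hydrogen-bond detection."""

    max_heavy_distance: float = 3.5  # Angstrom
    min_heavy_distance: float = 2.4  # Angstrom
    min_angle_proxy: float = 90.0  # degrees, antecedent-donor-acceptor

    def __post_init__(self) -> None:
        if not 0 < self.min_heavy_distance < self.max_heavy_distance:
            raise ValueError("require 0 < min_heavy_distance < max_heavy_distance")


@dataclass(frozen=True)
class PolarAtom:
    """A donor/acceptor heavy atom with its residue context."""

    residue: Residue
    atom: Atom
    role: str  # donor | acceptor | both
    antecedent: Atom | None  # covalently bonded heavy atom (angle proxy)
    is_water: bool

    @property
    def position(self) -> np.ndarray:
        return self.atom.position


@dataclass(frozen=True)
class HBond:
    """An unordered polar-atom pair satisfying the geometric criteria."""

    a: PolarAtom
    b: PolarAtom
    distance: float
    angle_proxy: float | None  # degrees; None when both partners are waters

    def residues(self) -> tuple[Residue, Residue]:
        return self.a.residue, self.b.residue


def load_ligand_definitions(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a ligand polar-atom definitions TSV: ``resname  atomname  role``."""
    defs: dict[str, dict[str, str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "resname":
            continue
        if len(parts) != 3 or parts[2] not in ("donor", "acceptor", "both"):
            raise ValueError(f"malformed ligand definition line: {line!r}")
        defs.setdefault(parts[0], {})[parts[1]] = parts[2]
    return defs


def polar_atom_table(
    residue_name: str,
    custom_defs: dict[str, dict[str, str]] | None = None,
) -> dict[str, str]:
    """Donor/acceptor roles of the heavy atoms of one residue type.

    Unknown residues without a custom definition are treated as apolar
    (with a warning).
    """
    if custom_defs and residue_name in custom_defs:
        return dict(custom_defs[residue_name])
    if residue_name in ("HOH", "WAT", "DOD"):
        return dict(WATER_ATOM_ROLES)
    if residue_name in _STANDARD_AA:
        roles = dict(_BACKBONE_ROLES)
        if residue_name == "PRO":
            del roles["N"]  # tertiary amide: no donor proton
        roles.update(_SIDECHAIN_ROLES.get(residue_name, {}))
        return roles
    warnings.warn(f"unknown residue {residue_name!r}: treated as apolar", stacklevel=2)
    return {}


def collect_polar_atoms(
    model: StructureModel,
    custom_defs: dict[str, dict[str, str]] | None = None,
) -> list[PolarAtom]:
    polar: list[PolarAtom] = []
    for res in model.residues:
        roles = polar_atom_table(res.name, custom_defs)
        if not roles:
            continue
        for atom in res.atoms:
            role = roles.get(atom.name)
            if role is None:
                continue
            ant_name = _ANTECEDENT_BY_RES.get((res.name, atom.name), _ANTECEDENT.get(atom.name))
            antecedent = res.atom(ant_name) if ant_name else None
            polar.append(
                PolarAtom(
                    residue=res,
                    atom=atom,
                    role=role,
                    antecedent=antecedent,
                    is_water=res.is_water,
                )
            )
    return polar


def _angle_deg(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - vertex
    v2 = p2 - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _donor_geometry_ok(donor: PolarAtom, acceptor_pos: np.ndarray, min_angle: float) -> tuple[bool, float | None]:
    """Angle proxy at the donor: antecedent-donor-acceptor >= min_angle.

    Waters (freely rotatable) and donors without a located antecedent pass
    unconditionally.
    """
    if donor.is_water or donor.antecedent is None:
        return True, None
    ang = _angle_deg(donor.antecedent.position, donor.position, acceptor_pos)
    return ang >= min_angle, ang


def _pair_is_bond(
    pa: PolarAtom, pb: PolarAtom, criteria: HBondCriteria
) -> tuple[bool, float | None]:
    """Check role compatibility + angle proxy for an in-window pair.

    The pair bonds if some donor/acceptor assignment is geometrically
    feasible; the reported angle is the donor-side angle of the first
    feasible assignment.
    """
    for donor, acceptor in ((pa, pb), (pb, pa)):
        if donor.role not in ("donor", "both"):
            continue
        if acceptor.role not in ("acceptor", "both"):
            continue
        ok, ang = _donor_geometry_ok(donor, acceptor.position, criteria.min_angle_proxy)
        if ok:
            return True, ang
    return False, None


def find_hbonds(
    model: StructureModel,
    criteria: HBondCriteria | None = None,
    custom_defs: dict[str, dict[str, str]] | None = None,
) -> list[HBond]:
    """All hydrogen bonds in a model under heavy-atom geometric criteria.

    Pairs within the same residue are never bonds; each unordered pair is
    reported once.  Returns an empty list when nothing qualifies.
    """
    criteria = criteria or HBondCriteria()
    polar = collect_polar_atoms(model, custom_defs)
    if len(polar) < 2:
        return []
    coords = np.array([p.position for p in polar])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=criteria.max_heavy_distance, output_type="ndarray")
    bonds: list[HBond] = []
    for i, j in pairs:
        pa, pb = polar[i], polar[j]
        if pa.residue is pb.residue:
            continue
        d = float(np.linalg.norm(pa.position - pb.position))
        if d < criteria.min_heavy_distance:
            continue
        ok, ang = _pair_is_bond(pa, pb, criteria)
        if ok:
            bonds.append(HBond(a=pa, b=pb, distance=d, angle_proxy=ang))
    bonds.sort(key=_bond_sort_key)
    return bonds


def _bond_sort_key(b: HBond):
    ka = (b.a.residue.chain, b.a.residue.seq_number, b.a.atom.name)
    kb = (b.b.residue.chain, b.b.residue.seq_number, b.b.atom.name)
    return tuple(sorted((ka, kb)))


def filter_backbone_helical(bonds: Iterable[HBond], min_separation: int = 5) -> list[HBond]:
    """Drop backbone-backbone bonds between residues closer than ``min_separation``.

    Removes the i -> i+4 helical hydrogen bonds of the scaffold, which never
    involve waters and are not part of the networks of interest.
    """
    kept = []
    for b in bonds:
        both_backbone = b.a.atom.name in ("N", "O") and b.b.atom.name in ("N", "O")
        same_chain = b.a.residue.chain == b.b.residue.chain
        if both_backbone and same_chain and not b.a.is_water and not b.b.is_water:
            if abs(b.a.residue.seq_number - b.b.residue.seq_number) < min_separation:
                continue
        kept.append(b)
    return kept
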