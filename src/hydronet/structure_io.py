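"""Structure and annotation I/O.

Reads and writes PDB-format coordinate files, resolves alternate locations,
identifies waters, manages model ensembles with per-model energies, and loads
the residue annotation overlay (Ballesteros-Weinstein generic numbers, helix
index 1-7 and the static/switchable helix class).

Residues are always keyed by author numbering as printed in the PDB file;
generic numbers are an overlay, never a substitute key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd

#: Residue names recognised as water.
WATER_RESNAMES: tuple[str, ...] = ("HOH", "WAT", "DOD")

VALID_CLASSES = ("static", "switchable", "none")


class StructureError(ValueError):
    """Raised for unparseable or empty structure input."""


class AnnotationError(ValueError):
    """Raised for malformed or self-contradictory annotation tables."""


class MissingEnergyError(ValueError):
    """Raised when an ensemble operation requires per-model energies."""


@dataclass
class Atom:
    """One atom of a structural model.

    ``record_kind`` distinguishes polymer atoms, generic hetero atoms and
    water atoms (by residue name).
    """

    serial: int
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    record_kind: str = "polymer"  # polymer | hetero | water

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    chain: str
    seq_number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_number, self.icode)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_RESNAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """A single coordinate model, optionally carrying an energy in REU."""

    model_id: str
    residues: list[Residue]
    energy: float | None = None
    source: str = ""

    @property
    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.is_water]

    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_water]

    def residue(self, chain: str, seq_number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.chain == chain and r.seq_number == seq_number and r.icode == icode:
                return r
        return None

    def all_atoms(self) -> Iterable[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a


@dataclass
class Ensemble:
    models: list[StructureModel]

    def __post_init__(self) -> None:
        if not self.models:
            raise StructureError("ensemble must contain at least one model")
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise StructureError("ensemble model_ids must be unique")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


@dataclass(frozen=True)
class HelixSegment:
    helix_id: int
    chain: str
    start: int
    end: int
    helix_class: str  # static | switchable

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"helix {self.helix_id}: start > end")


@dataclass(frozen=True)
class AnnotationEntry:
    bw_code: str
    helix_id: int | None
    helix_class: str  # static | switchable | none


class BWAnnotation:
    """Residue annotation overlay: (chain, resnum) -> generic number / helix / class."""

    def __init__(
        self,
        entries: Mapping[tuple[str, int], AnnotationEntry] | None = None,
        segments: list[HelixSegment] | None = None,
    ) -> None:
        self.entries: dict[tuple[str, int], AnnotationEntry] = dict(entries or {})
        self.segments: list[HelixSegment] = list(segments or [])

    def lookup(self, chain: str, seq_number: int) -> AnnotationEntry | None:
        return self.entries.get((chain, seq_number))

    def __len__(self) -> int:
        return len(self.entries)


def _parse_bw(bw: str) -> tuple[int, str]:
    """Validate an H.pos generic-number string; return (helix, position)."""
    parts = bw.split(".")
    if len(parts) != 2 or not parts[0].isdigit() or not parts[1].isdigit():
        raise AnnotationError(f"malformed Ballesteros-Weinstein code: {bw!r}")
    return int(parts[0]), parts[1]


def load_annotation(path: str | Path) -> BWAnnotation:
    """Load a residue annotation TSV.

    Expected header: ``chain  resnum  bw  helix  class`` (tab-separated,
    '#' comment lines skipped).  ``helix`` may be empty/'none' for
    unannotated residues; ``class`` must be static, switchable or none.
    Exact duplicate rows are deduplicated; conflicting duplicates raise
    :class:`AnnotationError`.
    """
    required = {"chain", "resnum", "bw", "helix", "class"}
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        # an entirely empty file yields an empty annotation
        return BWAnnotation()
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation missing columns: {sorted(missing)}")

    entries: dict[tuple[str, int], AnnotationEntry] = {}
    rows = zip(df["chain"], df["resnum"], df["bw"], df["helix"], df["class"])
    for chain, resnum_s, bw, helix_field, cls in rows:
        chain = str(chain)
        try:
            resnum = int(resnum_s)
        except ValueError as exc:
            raise AnnotationError(f"non-integer resnum {resnum_s!r}") from exc
        cls = str(cls).strip() or "none"
        if cls not in VALID_CLASSES:
            raise AnnotationError(f"invalid class {cls!r} for {chain}{resnum}")
        bw = str(bw).strip()
        helix_field = str(helix_field).strip()
        helix_id: int | None = None
        if helix_field and helix_field.lower() != "none":
            helix_id = int(helix_field)
        if bw and bw.lower() != "none":
            bw_helix, _ = _parse_bw(bw)
            if helix_id is not None and bw_helix != helix_id:
                raise AnnotationError(
                    f"helix {helix_id} inconsistent with code {bw} at {chain}{resnum}"
                )
        entry = AnnotationEntry(bw_code=bw, helix_id=helix_id, helix_class=cls)
        key = (chain, resnum)
        if key in entries and entries[key] != entry:
            raise AnnotationError(f"conflicting duplicate annotation for {chain}{resnum}")
        entries[key] = entry

    segments = _segments_from_entries(entries)
    return BWAnnotation(entries, segments)


def _segments_from_entries(
    entries: Mapping[tuple[str, int], AnnotationEntry]
) -> list[HelixSegment]:
    by_helix: dict[tuple[str, int], list[int]] = {}
    classes: dict[tuple[str, int], str] = {}
    for (chain, resnum), e in entries.items():
        if e.helix_id is None:
            continue
        by_helix.setdefault((chain, e.helix_id), []).append(resnum)
        classes[(chain, e.helix_id)] = e.helix_class
    segments = []
    for (chain, helix_id), resnums in sorted(by_helix.items()):
        segments.append(
            HelixSegment(
                helix_id=helix_id,
                chain=chain,
                start=min(resnums),
                end=max(resnums),
                helix_class=classes[(chain, helix_id)],
            )
        )
    return segments


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept: list[Atom] = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
        kept.append(best)
    kept.sort(key=lambda a: a.serial)
    return kept


def read_structure(
    path: str | Path,
    model_index: int = 0,
    water_resnames: tuple[str, ...] = WATER_RESNAMES,
) -> StructureModel:
    """Read one model from a PDB (or mmCIF) file.

    Waters are identified by residue name; altloc conflicts are resolved by
    keeping the highest-occupancy conformer (ties: alphabetically first
    altloc).  Multi-MODEL files return ``model_index`` (default: first).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    if model_index >= len(st):
        raise StructureError(f"{path}: model index {model_index} out of range")
    gmodel = st[model_index]

    residues: list[Residue] = []
    n_atoms = 0
    for chain in gmodel:
        for gres in chain:
            is_water = gres.name in water_resnames
            atoms = []
            for ga in gres:
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=ga.altloc if ga.altloc != "\x00" else "",
                        record_kind="water"
                        if is_water
                        else ("hetero" if gres.het_flag == "H" else "polymer"),
                    )
                )
            atoms = _resolve_altlocs(atoms)
            n_atoms += len(atoms)
            residues.append(
                Residue(
                    chain=chain.name,
                    seq_number=gres.seqid.num,
                    icode=gres.seqid.icode.strip(),
                    name=gres.name,
                    atoms=atoms,
                )
            )
    if n_atoms == 0:
        raise StructureError(f"{path}: structure contains zero atoms")
    return StructureModel(model_id=path.stem, residues=residues, source=str(path))


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as a standard PDB file (waters as HETATM, 3-decimal coords)."""
    if not model.residues:
        raise StructureError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 0
    for res in model.residues:
        chain = chains.get(res.chain)
        if chain is None:
            chain = gemmi.Chain(res.chain)
            chains[res.chain] = chain
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seq_number, res.icode or " ")
        gres.het_flag = "H" if res.is_water or res.name in ("NA", "K", "CL") else "A"
        for a in res.atoms:
            serial += 1
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*np.round(a.position, 3))
            ga.occ = a.occupancy
            ga.serial = serial
            if a.altloc:
                ga.altloc = a.altloc
            gres.add_atom(ga)
        chain.add_residue(gres)
    for chain in chains.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


def load_ensemble(manifest_path: str | Path) -> Ensemble:
    """Load an ensemble from a manifest TSV with columns ``path`` and ``energy_REU``.

    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", comment="#")
    models = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        m = read_structure(p)
        energy = getattr(row, "energy_REU", None)
        if energy is not None and not pd.isna(energy):
            m.energy = float(energy)
        models.append(m)
    return Ensemble(models)


def select_lowest_fraction(ensemble: Ensemble, fraction: float = 0.10) -> Ensemble:
    """Return the lowest-energy ``fraction`` of models.

    Keeps ``ceil(fraction * N)`` models (never fewer than one); ties are
    broken by input order.  Every model must carry an energy.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    for m in ensemble:
        if m.energy is None or not math.isfinite(m.energy):
            raise MissingEnergyError(f"model {m.model_id} has no finite energy")
    k = max(1, math.ceil(fraction * len(ensemble)))
    order = sorted(range(len(ensemble)), key=lambda i: (ensemble.models[i].energy, i))
    keep = sorted(order[:k])
    return Ensemble([ensemble.models[i] for i in keep])
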