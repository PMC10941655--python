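"""Macromolecular structure I/O and a light hierarchical coordinate model.

Structures are read and written through gemmi (fixed-column PDB and mmCIF
``atom_site`` dialects) and exposed as plain dataclasses. Author residue
numbering is the public residue identifier throughout the package, because
design targets are reported in author numbering (e.g. A775).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

from .chem import AA3_TO_1, NONSTANDARD_PARENT


class StructureError(ValueError):
    """Raised for unreadable, empty or format-violating structures."""


@dataclass
class Atom:
    """A single atom with coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be 3 finite numbers")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """A residue identified by author numbering plus optional insertion code."""

    chain_id: str
    seq_id: int
    name: str
    atoms: list[Atom]
    icode: str = ""

    @property
    def rid(self):
        """Public residue identifier: int, or "123A" string with insertion code."""
        return self.seq_id if not self.icode else f"{self.seq_id}{self.icode}"

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    entity_label: str = ""

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, rid) -> Residue | None:
        for r in self.residues:
            if r.rid == rid:
                return r
        return None

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        rows = [a.coords for r in self.residues for a in r.atoms
                if not heavy_only or a.is_heavy]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def translate(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, dtype=float)
        for r in self.residues:
            for a in r.atoms:
                a.coords = a.coords + vec

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        for r in self.residues:
            for a in r.atoms:
                a.coords = rotation @ a.coords + translation


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate chain ids in structure {self.id}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(
    path: str | Path,
    format: str = "auto",
    *,
    keep_hydrogens: bool = False,
    keep_waters: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is used; alternate locations are collapsed to the
    highest-occupancy conformer (ties by altloc letter); hydrogens and
    waters are dropped unless requested.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if format not in fmt_map:
        raise StructureError(f"unknown format {format!r}; expected pdb|mmcif|auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    source_format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format != "auto":
        source_format = format

    if len(st) == 0:
        raise StructureError(f"{path}: structure contains no models")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if not keep_waters and gres.name in _WATER_NAMES:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if not keep_hydrogens and ga.element.name in ("H", "D"):
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(Atom(
                    name=name,
                    element=ga.element.name.upper() or "X",
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                ))
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            residues.append(Residue(
                chain_id=gchain.name, seq_id=gres.seqid.num,
                name=gres.name, atoms=atoms, icode=icode,
            ))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))

    if not chains:
        raise StructureError(f"{path}: no atoms after filtering (empty structure)")

    metadata = {"title": st.name}
    if st.resolution > 0:
        metadata["resolution"] = st.resolution
    return Structure(
        id=st.name or path.stem, chains=chains,
        source_format=source_format, metadata=metadata,
    )


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a :class:`Structure` as fixed-column PDB or mmCIF.

    Author numbering and insertion codes are preserved. PDB output rejects
    chain ids longer than one character (format column limit).
    """
    if not structure.chains or structure.n_atoms() == 0:
        raise StructureError("refusing to write an empty structure")
    if format not in ("pdb", "mmcif"):
        raise StructureError(f"unknown format {format!r}; expected pdb|mmcif")
    if format == "pdb":
        bad = [c.chain_id for c in structure.chains if len(c.chain_id) > 1]
        if bad:
            raise StructureError(
                f"chain ids {bad} exceed the single-character PDB limit; use mmcif")
    st = _to_gemmi(structure)
    path = str(path)
    if format == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


def extract_sequence(chain: Chain, mode: str = "strict") -> str:
    """One-letter sequence of a chain in author residue order.

    ``strict`` maps every nonstandard residue to X; ``mapped`` first maps
    common modified residues (MSE, SEP, ...) to their standard parent.
    Chain breaks are not padded: one letter per modelled residue.
    """
    if not chain.residues:
        raise StructureError(f"chain {chain.chain_id}: empty chain has no sequence")
    if mode not in ("strict", "mapped"):
        raise ValueError(f"unknown mode {mode!r}")
    letters = []
    for res in chain.residues:
        if res.name in AA3_TO_1:
            letters.append(AA3_TO_1[res.name])
        elif mode == "mapped" and res.name in NONSTANDARD_PARENT:
            letters.append(NONSTANDARD_PARENT[res.name])
        else:
            letters.append("X")
    return "".join(letters)
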