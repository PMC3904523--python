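"""Protein structure handling: PDB input, atom normalization, pharmacophore
typing and relative solvent accessibility.

The structural unit of the signature method is the heavy atom.  A parsed
:class:`ProteinStructure` therefore holds hydrogen-free, water-free atoms;
non-protein hetero atoms (nucleic acids, ligands, ions) are retained and
flagged so that residue environments at protein–DNA interfaces include the
DNA atoms.  Every atom is assigned exactly one of eight pharmacophore
classes (hydrophobic, positive, negative, hydrogen acceptor, hydrogen
donor, aromatic, sulphur, neutral) through a table shipped with the
package; ambiguous atoms are resolved by a fixed priority order documented
in the table file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .errors import (
    EmptyStructureError,
    PDBParseError,
    UnknownAtomError,
    UnsupportedResidueError,
)

# Canonical ordering of the eight pharmacophore classes; all count vectors
# and pair-class layouts follow this order.
PHARMACOPHORE_CLASSES: Tuple[str, ...] = (
    "hydrophobic",
    "positive",
    "negative",
    "hydrogen_acceptor",
    "hydrogen_donor",
    "aromatic",
    "sulphur",
    "neutral",
)

#: polar/hydrophobic dichotomy used by the binary atom-classification scheme
BINARY_CLASS_OF: Dict[str, str] = {
    "hydrophobic": "hydrophobic",
    "aromatic": "hydrophobic",
    "neutral": "hydrophobic",
    "sulphur": "hydrophobic",
    "positive": "polar",
    "negative": "polar",
    "hydrogen_acceptor": "polar",
    "hydrogen_donor": "polar",
}

STANDARD_RESIDUES: Tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: Dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_HYDROGEN_ELEMENTS = {"H", "D"}

_METAL_ELEMENTS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "AL",
}
_HALOGEN_ELEMENTS = {"F", "CL", "BR", "I"}

#: residue key: (chain_id, residue_number, insertion_code)
ResidueKey = Tuple[str, int, str]


@dataclass
class AtomRecord:
    """One heavy atom of a normalized structure."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray
    insertion_code: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    hetero: bool = False
    pharmacophore: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.atom_name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.atom_name}: element must be non-empty")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class ProteinStructure:
    """An ordered list of heavy atoms plus a residue index.

    The residue index maps ``(chain_id, residue_number, insertion_code)``
    to the atoms of that residue, in file order.
    """

    structure_id: str
    atoms: List[AtomRecord]
    _residue_index: Dict[ResidueKey, List[AtomRecord]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        index: Dict[ResidueKey, List[AtomRecord]] = {}
        for atom in self.atoms:
            index.setdefault(atom.residue_key, []).append(atom)
        self._residue_index = index

    @property
    def residue_index(self) -> Dict[ResidueKey, List[AtomRecord]]:
        return self._residue_index

    def residue_atoms(self, residue: ResidueKey) -> List[AtomRecord]:
        key = _normalize_key(residue)
        if key not in self._residue_index:
            raise KeyError(f"residue {key} not found in structure {self.structure_id}")
        return self._residue_index[key]

    def residue_name(self, residue: ResidueKey) -> str:
        return self.residue_atoms(residue)[0].residue_name

    def residues(self) -> List[ResidueKey]:
        return list(self._residue_index)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_atoms(self, atoms: List[AtomRecord]) -> "ProteinStructure":
        return ProteinStructure(self.structure_id, atoms)


def _normalize_key(residue: ResidueKey | Tuple[str, int]) -> ResidueKey:
    if len(residue) == 2:
        chain, number = residue  # type: ignore[misc]
        return (str(chain), int(number), "")
    chain, number, icode = residue  # type: ignore[misc]
    return (str(chain), int(number), str(icode or "").strip())


class PharmacophoreTable:
    """Mapping ``(residue_name, atom_name) -> pharmacophore class``.

    Covers every heavy atom of the 20 standard amino acids (plus the
    C-terminal OXT).  Atoms outside the table — hetero atoms, non-standard
    residues — fall back to an element-based assignment so that nucleic
    acids and ligands in a residue environment still carry a class.
    """

    def __init__(self, mapping: Dict[Tuple[str, str], str]):
        for (res, atom), cls in mapping.items():
            if cls not in PHARMACOPHORE_CLASSES:
                raise ValueError(f"unknown class {cls!r} for {res} {atom}")
        self._mapping = dict(mapping)
        self._inventories: Dict[str, List[str]] = {}
        for (res, atom) in self._mapping:
            if atom != "OXT":
                self._inventories.setdefault(res, []).append(atom)

    @classmethod
    def default(cls) -> "PharmacophoreTable":
        return cls(_load_pharmacophore_file(_data_path("pharmacophores.tsv")))

    @classmethod
    def from_file(cls, path: str | Path) -> "PharmacophoreTable":
        return cls(_load_pharmacophore_file(Path(path)))

    def lookup(self, residue_name: str, atom_name: str, element: str = "") -> str:
        key = (residue_name.upper(), atom_name.upper())
        if key in self._mapping:
            return self._mapping[key]
        cls = element_fallback_class(element)
        if cls is None:
            raise UnknownAtomError(
                f"no pharmacophore class for atom {atom_name!r} of residue "
                f"{residue_name!r} (element {element!r})"
            )
        return cls

    def atom_inventory(self, residue_name: str) -> List[str]:
        """Canonical heavy atoms of a standard residue (OXT excluded)."""
        res = residue_name.upper()
        if res not in self._inventories:
            raise UnsupportedResidueError(f"unsupported residue {residue_name!r}")
        return list(self._inventories[res])

    def residue_vector(self, residue_name: str) -> np.ndarray:
        """8-vector of pharmacophore counts over the residue's heavy atoms."""
        counts = np.zeros(len(PHARMACOPHORE_CLASSES), dtype=int)
        for atom in self.atom_inventory(residue_name):
            cls = self._mapping[(residue_name.upper(), atom)]
            counts[PHARMACOPHORE_CLASSES.index(cls)] += 1
        return counts


def element_fallback_class(element: str) -> Optional[str]:
    """Element-based pharmacophore class for atoms outside the residue table.

    Documented fallback: C→hydrophobic, N→hydrogen_donor, O→hydrogen_acceptor,
    S/Se→sulphur, P→negative (phosphate backbone), metals→positive,
    halogens→negative, boron/silicon→neutral.  Returns None for elements with
    no sensible assignment.
    """
    el = element.upper().strip()
    if not el:
        return None
    if el == "C":
        return "hydrophobic"
    if el == "N":
        return "hydrogen_donor"
    if el == "O":
        return "hydrogen_acceptor"
    if el in ("S", "SE"):
        return "sulphur"
    if el == "P":
        return "negative"
    if el in _METAL_ELEMENTS:
        return "positive"
    if el in _HALOGEN_ELEMENTS:
        return "negative"
    if el in ("B", "SI"):
        return "neutral"
    return None


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def _load_pharmacophore_file(path: Path) -> Dict[Tuple[str, str], str]:
    mapping: Dict[Tuple[str, str], str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, cls = line.split("\t")
        mapping[(res.upper(), atom.upper())] = cls
    return mapping


def load_max_asa(path: Optional[Path] = None) -> Dict[str, float]:
    """Per-residue maximum accessible surface area reference, in Å²."""
    path = path or _data_path("max_asa.tsv")
    table: Dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, area = line.split("\t")
        table[res.upper()] = float(area)
    return table


# ---------------------------------------------------------------------------
# PDB input / output


def read_pdb(
    path: str | Path,
    structure_id: Optional[str] = None,
    keep_hetero: bool = True,
) -> ProteinStructure:
    """Parse a PDB file into a normalized :class:`ProteinStructure`.

    Normalization policy: first model only; hydrogens and waters removed;
    for alternate locations only the highest-occupancy conformer is kept
    (tie broken by file order); hetero atoms kept but flagged unless
    ``keep_hetero`` is false.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    sid = structure_id or path.stem
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(sid, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise EmptyStructureError(f"{path}: no models found")
    model = models[0]

    atoms: List[AtomRecord] = []
    n_protein = 0
    for chain in model:
        for residue in chain:
            hetfield, resseq, icode = residue.id
            resname = residue.get_resname().strip().upper()
            hetero = hetfield.strip() != ""
            if resname in _WATER_NAMES or hetfield == "W":
                continue
            if hetero and not keep_hetero:
                continue
            for atom in _select_altlocs(residue.get_unpacked_list()):
                element = (atom.element or "").strip().upper()
                if element in _HYDROGEN_ELEMENTS:
                    continue
                if not element:
                    element = atom.get_name().strip()[:1].upper()
                record = AtomRecord(
                    serial=atom.get_serial_number() or 0,
                    atom_name=atom.get_name().strip(),
                    element=element,
                    residue_name=resname,
                    residue_number=int(resseq),
                    chain_id=str(chain.id),
                    coords=np.asarray(atom.get_coord(), dtype=float),
                    insertion_code=icode.strip(),
                    altloc="",
                    occupancy=float(atom.get_occupancy() or 1.0),
                    hetero=hetero,
                )
                atoms.append(record)
                if not hetero:
                    n_protein += 1
    if n_protein == 0:
        raise EmptyStructureError(f"{path}: no protein atoms after normalization")
    return ProteinStructure(sid, atoms)


def _select_altlocs(bio_atoms: Iterable) -> List:
    """Keep one conformer per atom name: highest occupancy, tie → first seen."""
    best: Dict[str, object] = {}
    order: List[str] = []
    for atom in bio_atoms:
        name = atom.get_name()
        occ = atom.get_occupancy()
        occ = 1.0 if occ is None else float(occ)
        if name not in best:
            best[name] = atom
            order.append(name)
        else:
            cur = best[name]
            cur_occ = cur.get_occupancy()
            cur_occ = 1.0 if cur_occ is None else float(cur_occ)
            if occ > cur_occ:
                best[name] = atom
    return [best[name] for name in order]


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a normalized structure back out as PDB text."""
    Path(path).write_text(structure_to_pdb_text(structure))


def structure_to_pdb_text(structure: ProteinStructure) -> str:
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        record = "HETATM" if atom.hetero else "ATOM  "
        name = atom.atom_name
        # column alignment per wwPDB: 1-char elements start in column 14
        if len(atom.element) == 1 and len(name) < 4:
            name_field = f" {name:<3s}"
        else:
            name_field = f"{name:<4s}"
        x, y, z = atom.coords
        lines.append(
            f"{record}{i:5d} {name_field} {atom.residue_name:<3s} "
            f"{atom.chain_id[:1]:1s}{atom.residue_number:4d}"
            f"{(atom.insertion_code or ' '):1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pharmacophore assignment


def assign_pharmacophores(
    structure: ProteinStructure, table: Optional[PharmacophoreTable] = None
) -> ProteinStructure:
    """Return a copy of the structure with every atom labelled.

    Standard-residue atoms are labelled by table lookup; everything else
    (hetero atoms, non-standard residues) by the element fallback.
    """
    table = table or PharmacophoreTable.default()
    labelled = []
    for atom in structure.atoms:
        cls = table.lookup(atom.residue_name, atom.atom_name, atom.element)
        labelled.append(replace(atom, coords=atom.coords.copy(), pharmacophore=cls))
    return structure.with_atoms(labelled)


def residue_pharmacophore_vector(
    residue_name: str, table: Optional[PharmacophoreTable] = None
) -> np.ndarray:
    """Pharmacophore count vector *p* of one standard residue.

    Entry order follows :data:`PHARMACOPHORE_CLASSES`; the entries sum to
    the residue's heavy-atom count.
    """
    table = table or PharmacophoreTable.default()
    return table.residue_vector(residue_name)


# ---------------------------------------------------------------------------
# Solvent accessibility

_SASA_POINTS = 1000


def _to_biotite_array(structure: ProteinStructure):
    import biotite.structure as struc

    n = len(structure.atoms)
    array = struc.AtomArray(n)
    array.coord = structure.coords_array().astype(np.float32)
    array.chain_id = np.array([a.chain_id for a in structure.atoms])
    array.res_id = np.array([a.residue_number for a in structure.atoms])
    array.ins_code = np.array([a.insertion_code for a in structure.atoms])
    array.res_name = np.array([a.residue_name for a in structure.atoms])
    array.atom_name = np.array([a.atom_name for a in structure.atoms])
    array.element = np.array([a.element for a in structure.atoms])
    array.hetero = np.array([a.hetero for a in structure.atoms])
    return array


def _atom_sasa(structure: ProteinStructure, probe_radius: float) -> np.ndarray:
    """Shrake–Rupley accessible surface per atom (element-based vdW radii)."""
    import biotite.structure as struc

    array = _to_biotite_array(structure)
    areas = struc.sasa(
        array,
        probe_radius=probe_radius,
        vdw_radii="Single",
        point_number=_SASA_POINTS,
    )
    return np.nan_to_num(np.asarray(areas, dtype=float), nan=0.0)


def compute_rsa(
    structure: ProteinStructure,
    residue: ResidueKey,
    probe_radius: float = 1.4,
    max_asa: Optional[Dict[str, float]] = None,
) -> float:
    """Relative solvent accessibility of one residue, clipped to [0, 1].

    The residue's accessible surface area (rolling probe, default 1.4 Å)
    is divided by the per-residue maximum-accessibility reference value.
    """
    return compute_rsa_all(structure, probe_radius, max_asa)[_normalize_key(residue)]


def compute_rsa_all(
    structure: ProteinStructure,
    probe_radius: float = 1.4,
    max_asa: Optional[Dict[str, float]] = None,
) -> Dict[ResidueKey, float]:
    """RSA for every standard residue of the structure in one SASA pass.

    Non-standard residues are omitted (they have no reference maximum).
    """
    max_asa = max_asa or load_max_asa()
    areas = _atom_sasa(structure, probe_radius)
    per_residue: Dict[ResidueKey, float] = {}
    for atom, area in zip(structure.atoms, areas):
        per_residue[atom.residue_key] = per_residue.get(atom.residue_key, 0.0) + area
    out: Dict[ResidueKey, float] = {}
    for key, asa in per_residue.items():
        resname = structure.residue_name(key)
        if resname in max_asa:
            out[key] = min(asa / max_asa[resname], 1.0)
    return out
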