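"""Reading atomic models, selections, and per-atom constants.

Structures are read from PDB or mmCIF files (via gemmi) into a flat,
numpy-friendly :class:`StructureModel`.  Only the first model block of a
multi-model file is used.  Alternate locations are collapsed to the
highest-occupancy conformer (ties broken by file order); hydrogens and
HETATM records are excluded by default, matching what deposited cryo-EM
models of large proteins actually contain.

Per-atom van der Waals radii come from a Bondi-type table shipped here as
:data:`VDW_RADII`; per-residue hydropathy values are the Kyte-Doolittle
scale (:data:`KYTE_DOOLITTLE`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("bltpgeom")

# ---------------------------------------------------------------------------
# Constant tables
# ---------------------------------------------------------------------------

#: Bondi-type van der Waals radii in Angstrom, keyed by element symbol.
VDW_RADII: dict[str, dict[str, float]] = {
    "bondi": {
        "C": 1.70,
        "N": 1.55,
        "O": 1.52,
        "S": 1.80,
        "P": 1.80,
        "H": 1.20,
    },
}

#: Fallback radius (Angstrom) for elements missing from the table.
DEFAULT_VDW_RADIUS = 1.70

#: Kyte-Doolittle hydropathy scale; higher = more hydrophobic.
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

#: Sentinel for residues outside the hydropathy table; excluded from means.
HYDROPATHY_UNKNOWN = float("nan")


def hydropathy(residue_name: str, table: dict[str, float] | None = None) -> float:
    """Hydropathy of a 3-letter residue code; NaN for non-standard residues."""
    tab = KYTE_DOOLITTLE if table is None else table
    return tab.get(residue_name.upper(), HYDROPATHY_UNKNOWN)


class BltpGeomError(Exception):
    """Base class for errors raised by this package."""


class ParseError(BltpGeomError):
    """Structure file could not be read."""


class EmptyModelError(BltpGeomError):
    """No atoms survived parsing/filtering."""


class EmptySelectionError(BltpGeomError):
    """A selection matched zero atoms."""


class ConfigError(BltpGeomError):
    """Unknown named table or invalid parameter value."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of a model; residue numbering is kept exactly as read."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: tuple[float, float, float]
    vdw_radius: float
    occupancy: float = 1.0
    is_hetero: bool = False


@dataclass
class StructureModel:
    """An ordered collection of atoms plus provenance."""

    atoms: list[AtomRecord]
    source_id: str = ""
    title: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyModelError(f"model from {self.source_id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of positions in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        """(N,) float array of van der Waals radii in Angstrom."""
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen


@dataclass(frozen=True)
class Selection:
    """Chain + inclusive residue-range selection, 1-based author numbering.

    ``chain_id`` may be ``"*"`` for any chain; an empty ``residue_ranges``
    means every residue of the chain.  String form: ``"A:10-50,70-90"``.
    """

    chain_id: str = "*"
    residue_ranges: tuple[tuple[int, int], ...] = ()
    atom_name_filter: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for lo, hi in self.residue_ranges:
            if lo > hi:
                raise ConfigError(f"invalid residue range [{lo}, {hi}]: start > end")

    @classmethod
    def from_string(cls, text: str) -> "Selection":
        """Parse ``"CHAIN:START-END[,START-END...]"``; ``"*"`` = any chain."""
        text = text.strip()
        if not text or text == "*":
            return cls()
        if ":" in text:
            chain, _, rest = text.partition(":")
        else:
            chain, rest = text, ""
        chain = chain.strip() or "*"
        ranges: list[tuple[int, int]] = []
        for part in filter(None, (p.strip() for p in rest.split(","))):
            m = re.fullmatch(r"(-?\d+)\s*-\s*(-?\d+)", part)
            if m:
                ranges.append((int(m.group(1)), int(m.group(2))))
            elif re.fullmatch(r"-?\d+", part):
                n = int(part)
                ranges.append((n, n))
            else:
                raise ConfigError(f"cannot parse residue range {part!r} in {text!r}")
        return cls(chain_id=chain, residue_ranges=tuple(ranges))

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain_id != "*" and atom.chain_id != self.chain_id:
            return False
        if self.residue_ranges and not any(
            lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.atom_name_filter is not None and atom.name not in self.atom_name_filter:
            return False
        return True


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _radius_for_element(element: str, table: dict[str, float]) -> float:
    r = table.get(element.upper().strip())
    if r is None:
        logger.warning(
            "element %r not in radii table; using default %.2f A",
            element, DEFAULT_VDW_RADIUS,
        )
        return DEFAULT_VDW_RADIUS
    return r


def _infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name when the element column is blank."""
    stripped = atom_name.strip()
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_structure(
    path: str | Path,
    format: str = "auto",
    *,
    include_hydrogens: bool = False,
    include_hetero: bool = False,
    radii_set: str = "bondi",
) -> StructureModel:
    """Read the first model of a PDB or mmCIF file.

    Parameters
    ----------
    path:
        Coordinate file.  ``format`` is ``"pdb"``, ``"mmcif"`` or ``"auto"``
        (detected from contents/extension).
    include_hydrogens, include_hetero:
        Whether to keep hydrogen atoms and HETATM records (waters, ligands).
        Both default to off: deposited cryo-EM models lack hydrogens, and
        the geometry stages operate on the polymer.
    radii_set:
        Name of the shipped van der Waals radii table.

    Only the highest-occupancy alternate location of each atom is kept
    (ties: first in file).  Residue numbering is never altered.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    fmt_map = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    try:
        fmt = fmt_map[format]
    except KeyError:
        raise ConfigError(f"unknown format {format!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if radii_set not in VDW_RADII:
        raise ConfigError(
            f"unknown radii set {radii_set!r}; available: {sorted(VDW_RADII)}"
        )
    table = VDW_RADII[radii_set]

    if len(st) == 0:
        raise EmptyModelError(f"{path} contains no model block")
    model = st[0]  # first MODEL block only

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            is_het = residue.het_flag == "H"
            if is_het and not include_hetero:
                continue
            # collapse altlocs: highest occupancy wins, first-in-file on ties
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in residue:
                if atom.name not in best:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > best[atom.name].occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                element = atom.element.name if atom.element.name != "X" else ""
                if not element:
                    element = _infer_element(atom.name)
                if element.upper() == "H" and not include_hydrogens:
                    continue
                atoms.append(AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=element,
                    residue_name=residue.name,
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    vdw_radius=_radius_for_element(element, table),
                    occupancy=atom.occ,
                    is_hetero=is_het,
                ))
    if not atoms:
        raise EmptyModelError(f"{path} parsed but yielded zero atoms after filtering")
    return StructureModel(atoms=atoms, source_id=str(path), title=st.name or "")


def apply_selection(model: StructureModel, sel: Selection) -> StructureModel:
    """Subset a model by chain/residue-range selection, preserving order."""
    kept = [a for a in model.atoms if sel.matches(a)]
    if not kept:
        raise EmptySelectionError(
            f"selection chain={sel.chain_id!r} ranges={list(sel.residue_ranges)} "
            f"matched no atoms in {model.source_id!r}"
        )
    return StructureModel(atoms=kept, source_id=model.source_id, title=model.title)


def assign_radii(model: StructureModel, radii_set: str = "bondi") -> StructureModel:
    """Return a copy with vdW radii (re)assigned from the named table."""
    if radii_set not in VDW_RADII:
        raise ConfigError(
            f"unknown radii set {radii_set!r}; available: {sorted(VDW_RADII)}"
        )
    table = VDW_RADII[radii_set]
    atoms = [
        replace(a, vdw_radius=_radius_for_element(a.element, table))
        for a in model.atoms
    ]
    return StructureModel(atoms=atoms, source_id=model.source_id, title=model.title)


def write_pdb(
    model: StructureModel,
    path: str | Path,
    remarks: Sequence[str] = (),
) -> None:
    """Write a model as a standard fixed-column PDB file (via gemmi).

    ``remarks`` are free-text lines emitted as REMARK 99 records, used by
    the synthetic generator to record its spec and seed.
    """
    # gemmi's add_residue/add_chain copy their argument, so each container
    # must be fully populated before insertion
    grouped: dict[str, list[list[AtomRecord]]] = {}
    for a in model.atoms:
        residues = grouped.setdefault(a.chain_id, [])
        if not residues or residues[-1][0].residue_number != a.residue_number:
            residues.append([a])
        else:
            residues[-1].append(a)
    st = gemmi.Structure()
    st.name = model.title or "bltpgeom"
    gmodel = gemmi.Model("1")
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for records in residues:
            residue = gemmi.Residue()
            residue.name = records[0].residue_name
            residue.seqid = gemmi.SeqId(records[0].residue_number, " ")
            residue.het_flag = "H" if records[0].is_hetero else "A"
            for a in records:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.position)
                atom.occ = a.occupancy
                atom.serial = a.serial
                residue.add_atom(atom)
            chain.add_residue(residue)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    wrapped: list[str] = []
    for line in remarks:
        text = str(line)
        while True:
            wrapped.append(f"REMARK  99 {text[:68]}")
            text = text[68:]
            if not text:
                break
    st.raw_remarks = wrapped
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())
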