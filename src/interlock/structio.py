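"""Structure and alignment I/O: multi-model PDB ensembles and aligned FASTA.

The shared data model is deliberately small: an :class:`Ensemble` is an
ordered list of :class:`Snapshot` objects with identical residue topology,
each snapshot an ordered list of residues with explicit atoms.  All
coordinates are in Ångström, residue numbering is 1-based PDB numbering,
and only protein ``ATOM`` records are considered (HETATM is skipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "Atom",
    "Residue",
    "Snapshot",
    "Ensemble",
    "Msa",
    "StructureError",
    "TopologyError",
    "AlignmentError",
    "read_pdb",
    "write_pdb",
    "read_fasta_alignment",
    "write_fasta_alignment",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: unified atomic masses for the elements that occur in protein heavy atoms
#: (plus hydrogen, present in some NMR ensembles)
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "SE": 78.971,
}

MSA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY-X")


class StructureError(ValueError):
    """Malformed structure file or invalid structural data."""


class TopologyError(StructureError):
    """Snapshots of one ensemble disagree in residue/atom topology."""


class AlignmentError(ValueError):
    """Malformed alignment (ragged rows, duplicate ids, bad symbols)."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    is_backbone: bool = False
    mass: float = 12.011

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.mass > 0:
            raise StructureError(f"atom {self.name!r}: mass must be positive")


def make_atom(name: str, element: str, position: Sequence[float]) -> Atom:
    """Build an Atom, inferring backbone membership and mass from tables."""
    element = element.upper()
    mass = ELEMENT_MASSES.get(element, 12.011)
    return Atom(
        name=name,
        element=element,
        position=np.asarray(position, dtype=float),
        is_backbone=name in BACKBONE_NAMES,
        mass=mass,
    )


#: a residue identity within a snapshot
ResidueKey = tuple  # (chain_id, number, insertion_code)


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom]
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.chain_id}{self.number}: no atoms")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.number}{self.insertion_code}"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms if a.element != "H"], dtype=float)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Snapshot:
    residues: list[Residue]
    model_index: int = 1
    time: Optional[float] = None  # picoseconds

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (chain, number, insertion_code) in snapshot")

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> list[Residue]:
        out = [r for r in self.residues if r.chain_id == chain_id]
        if not out:
            raise KeyError(f"no chain {chain_id!r} in snapshot")
        return out

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == tuple(key):
                return r
        raise KeyError(f"no residue {key} in snapshot")

    def topology_signature(self) -> tuple:
        return tuple(
            (r.chain_id, r.number, r.insertion_code, r.name, tuple(a.name for a in r.atoms))
            for r in self.residues
        )

    def coordinates(self) -> np.ndarray:
        """All atom coordinates in residue/atom order, shape (n_atoms, 3)."""
        return np.concatenate([[a.position for a in r.atoms] for r in self.residues])

    def with_coordinates(self, coords: np.ndarray) -> "Snapshot":
        """Copy of this snapshot with all atom positions replaced (same order)."""
        coords = np.asarray(coords, dtype=float)
        residues = []
        k = 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(replace(a, position=coords[k].copy()))
                k += 1
            residues.append(Residue(r.chain_id, r.number, r.name, atoms, r.insertion_code))
        if k != len(coords):
            raise StructureError("coordinate array does not match snapshot atom count")
        return Snapshot(residues, model_index=self.model_index, time=self.time)


@dataclass
class Ensemble:
    snapshots: list[Snapshot]
    frame_spacing: Optional[float] = None  # picoseconds between frames

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise StructureError("ensemble must contain at least one snapshot")
        ref = self.snapshots[0].topology_signature()
        for snap in self.snapshots[1:]:
            if snap.topology_signature() != ref:
                raise TopologyError(
                    f"model {snap.model_index} has different residue/atom topology "
                    f"than model {self.snapshots[0].model_index}"
                )

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.snapshots)

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, i: int) -> Snapshot:
        return self.snapshots[i]


@dataclass
class Msa:
    """An aligned set of protein sequences over the 20 AA + gap alphabet."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if self.rows:
            n = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise AlignmentError(
                        f"sequence {sid!r} has length {len(row)}, expected {n}"
                    )
                bad = set(row) - MSA_ALPHABET
                if bad:
                    raise AlignmentError(f"sequence {sid!r}: invalid symbols {sorted(bad)}")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, i: int) -> str:
        """Column ``i`` (1-based) as a string."""
        return "".join(row[i - 1] for row in self.rows)


# ---------------------------------------------------------------------------
# PDB

def _convert_bio_model(model, model_index: int) -> Snapshot:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, number, icode = res.id
            if hetflag.strip():  # skip HETATM / waters
                continue
            atoms = []
            for atom in res:
                # alternate locations: Bio.PDB's DisorderedAtom already
                # selects the highest-occupancy conformer (first on ties)
                element = (atom.element or atom.get_name()[:1]).upper()
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=element,
                        position=np.asarray(atom.coord, dtype=float),
                        is_backbone=atom.get_name() in BACKBONE_NAMES,
                        mass=ELEMENT_MASSES.get(element, float(atom.mass) or 12.011),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.id,
                        number=int(number),
                        name=res.get_resname().strip(),
                        atoms=atoms,
                        insertion_code=icode.strip(),
                    )
                )
    if not residues:
        raise StructureError(f"model {model_index}: no protein ATOM records")
    return Snapshot(residues, model_index=model_index)


def read_pdb(path: str | Path, frame_spacing: Optional[float] = None) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    One snapshot per MODEL record; a file without MODEL records yields a
    single-snapshot ensemble.  HETATM records are ignored; alternate
    locations resolve to the highest-occupancy conformer.  Raises
    :class:`StructureError` on malformed records (with the offending line
    reported by the parser) and :class:`TopologyError` when models disagree
    in their residue/atom sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise StructureError(f"{path}: {exc}") from exc
    snapshots = [
        _convert_bio_model(model, model_index=k + 1)
        for k, model in enumerate(structure)
    ]
    if not snapshots:
        raise StructureError(f"{path}: no models found")
    return Ensemble(snapshots, frame_spacing=frame_spacing)


def _format_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    name = atom.name
    # PDB column convention: atom names of <4 chars start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.position
    return (
        f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.name:>3s} {res.chain_id:1s}"
        f"{res.number:4d}{res.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_pdb(ensemble: Ensemble | Snapshot, path: str | Path) -> None:
    """Write an ensemble as a standard PDB file.

    Multi-snapshot ensembles get MODEL/ENDMDL framing; a single snapshot is
    written as plain ATOM records.  Coordinates are written at PDB precision
    (3 decimals), so a read/write round trip agrees to 0.001 Å.
    """
    if isinstance(ensemble, Snapshot):
        ensemble = Ensemble([ensemble])
    path = Path(path)
    multi = len(ensemble) > 1
    lines: list[str] = []
    for snap in ensemble:
        if multi:
            lines.append(f"MODEL     {snap.model_index:4d}")
        serial = 0
        prev_chain = None
        for res in snap:
            if prev_chain is not None and res.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = res.chain_id
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line(serial, atom, res))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta_alignment(path: str | Path) -> Msa:
    """Read an aligned FASTA file; rows are upper-cased and length-checked."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids: list[str] = []
    rows: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(str(record.seq).upper().replace(".", "-"))
    if not ids:
        raise AlignmentError(f"{path}: no FASTA records")
    return Msa(ids=ids, rows=rows)


def write_fasta_alignment(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n")
            for k in range(0, len(row), 60):
                fh.write(row[k : k + 60] + "\n")
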