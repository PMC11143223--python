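"""Structure and trajectory I/O, atom selection, residue renumbering, alanine truncation.

All user-facing APIs take residue numbers in the *original* (crystal-structure)
numbering scheme.  Structures produced by MD pipelines are often renumbered from 1;
:class:`ResidueMap` translates between the two schemes so that a single canonical
numbering is used throughout, avoiding silent off-by-offset errors.

PDB is the only structure and trajectory format: a single-model file is a
:class:`Structure`, a multi-model (MODEL/ENDMDL) file is a :class:`Trajectory`.
Parsing and writing are delegated to :mod:`biotite.structure.io.pdb`; a thin
pre-scan adds precise line-number / model-index error reporting.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "ResidueMap",
    "PDBParseError",
    "FrameCongruenceError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "select",
    "truncate_to_alanine",
    "read_residue_map",
]

# Heavy atoms kept by an alanine truncation (CB retained when present).
_ALA_KEEP = frozenset({"N", "CA", "C", "O", "OXT", "CB"})

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class PDBParseError(ValueError):
    """Raised for malformed fixed-width PDB content (reports the line number)."""


class FrameCongruenceError(ValueError):
    """Raised when trajectory models disagree in atom count (reports the model index)."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, PDB-style.

    ``residue_seq`` is in the original numbering scheme; ``position`` is in Å.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    position: np.ndarray
    is_hetero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """An ordered collection of atoms with a label and a set of ligand residue codes."""

    atoms: list[AtomRecord]
    label: str = ""
    ligand_codes: frozenset[str] = frozenset()

    def __post_init__(self):
        self.atoms = list(self.atoms)
        self.ligand_codes = frozenset(self.ligand_codes)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array incongruent with atom count")
        new_atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Structure(new_atoms, label=self.label, ligand_codes=self.ligand_codes)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residue_numbers(self) -> list[int]:
        """Ordered unique residue numbers of non-hetero atoms."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if not a.is_hetero:
                seen.setdefault(a.residue_seq, None)
        return list(seen)


@dataclass
class Trajectory:
    """A topology plus an ordered frame series congruent with it.

    ``frames`` is an (n_frames, n_atoms, 3) array in Å; ``frame_spacing`` is the
    time per frame in ps, or ``None`` when unknown.
    """

    topology: Structure
    frames: np.ndarray
    frame_spacing: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise FrameCongruenceError(
                f"frames have {self.frames.shape[1]} atoms, topology has {len(self.topology)}"
            )
        if self.n_frames < 1:
            raise ValueError("a trajectory needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])


@dataclass
class ResidueMap:
    """Bijection between original and rearranged residue numbering.

    Explicit pairs win; when a number has no explicit pair and ``default_offset``
    is set, ``rearranged = original - default_offset``.
    """

    pairs: dict[int, int] = field(default_factory=dict)
    default_offset: int | None = None

    def __post_init__(self):
        rearranged = list(self.pairs.values())
        if len(set(rearranged)) != len(rearranged):
            raise ValueError("residue map is not one-to-one")
        self._reverse = {v: k for k, v in self.pairs.items()}

    def to_rearranged(self, original: int) -> int:
        if original in self.pairs:
            return self.pairs[original]
        if self.default_offset is not None:
            return original - self.default_offset
        raise KeyError(f"original residue {original} not mappable (no pair, no offset)")

    def to_original(self, rearranged: int) -> int:
        if rearranged in self._reverse:
            return self._reverse[rearranged]
        if self.default_offset is not None:
            return rearranged + self.default_offset
        raise KeyError(f"rearranged residue {rearranged} not mappable (no pair, no offset)")

    @classmethod
    def identity(cls) -> "ResidueMap":
        return cls(default_offset=0)


def map_residue_number(rmap: ResidueMap, number: int, direction: str) -> int:
    """Translate ``number`` ``"to_rearranged"`` or ``"to_original"``."""
    if direction == "to_rearranged":
        return rmap.to_rearranged(number)
    if direction == "to_original":
        return rmap.to_original(number)
    raise ValueError(f"unknown direction {direction!r}")


def read_residue_map(source) -> ResidueMap:
    """Read a residue map from 2-column delimited text (original, rearranged).

    A single line ``offset <int>`` is the single-offset shorthand
    (rearranged = original - offset).
    """
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    pairs: dict[int, int] = {}
    offset: int | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        fields = line.replace(",", " ").split()
        if fields[0].lower() == "offset":
            offset = int(fields[1])
            continue
        if len(fields) != 2:
            raise ValueError(f"residue map line {lineno}: expected 2 columns, got {len(fields)}")
        pairs[int(fields[0])] = int(fields[1])
    return ResidueMap(pairs=pairs, default_offset=offset)


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite-backed)
# ---------------------------------------------------------------------------


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    p = Path(source)
    if p.exists():
        return p.read_text()
    return str(source)


def _prescan(text: str) -> None:
    """Validate fixed-width coordinate fields, reporting exact line numbers."""
    model_counts: list[int] = []
    current = 0
    in_model = False
    n_atoms_total = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            n_atoms_total += 1
            current += 1
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated {rec} record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                    ) from None
            if line[26] not in (" ", ""):
                raise PDBParseError(
                    f"line {lineno}: insertion code {line[26]!r} not supported"
                )
        elif rec == "MODEL":
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            model_counts.append(current)
            current = 0
    if in_model and current:
        model_counts.append(current)
    if n_atoms_total == 0:
        raise PDBParseError("no ATOM/HETATM records found (empty structure)")
    if model_counts and len(set(model_counts)) > 1:
        ref = model_counts[0]
        for i, c in enumerate(model_counts[1:], start=2):
            if c != ref:
                raise FrameCongruenceError(
                    f"model {i} has {c} atoms, model 1 has {ref}"
                )


def _atom_array_to_records(arr: struc.AtomArray) -> list[AtomRecord]:
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    records = []
    for i in range(arr.array_length()):
        records.append(
            AtomRecord(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).capitalize(),
                residue_name=str(arr.res_name[i]),
                residue_seq=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]) or "A",
                position=arr.coord[i],
                is_hetero=bool(arr.hetero[i]),
            )
        )
    return records


def _load_pdb(text: str) -> struc.AtomArrayStack:
    pdb = PDBFile.read(io.StringIO(text))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = pdb.get_structure(altloc="first", extra_fields=["atom_id"])
    n_alt = 0
    try:
        altlocs = pdb.get_structure(model=1, altloc="all")
        n_alt = int(np.sum(~np.isin(altlocs.get_annotation("altloc_id"), (" ", "", "A"))))
    except Exception:  # pragma: no cover - altloc bookkeeping is best-effort
        pass
    if n_alt:
        logger.info("dropped %d alternate-location atoms (kept blank/'A')", n_alt)
    return stack


def read_pdb(source, label: str = "", ligand_codes: Iterable[str] = ()) -> Structure:
    """Read the first model of a PDB file or text stream into a :class:`Structure`.

    Hetero atoms are flagged from the HETATM record type; every HETATM residue
    name is additionally registered as an eligible ligand code.
    """
    text = _as_text(source)
    _prescan(text)
    stack = _load_pdb(text)
    arr = stack[0]
    records = _atom_array_to_records(arr)
    codes = set(ligand_codes) | {
        r.residue_name for r in records if r.is_hetero and r.residue_name != "HOH"
    }
    return Structure(records, label=label, ligand_codes=frozenset(codes))


def read_trajectory(source, topology: Structure | None = None,
                    frame_spacing: float | None = None) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory` (one frame per model)."""
    text = _as_text(source)
    _prescan(text)
    stack = _load_pdb(text)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    if topology is None:
        records = _atom_array_to_records(stack[0])
        codes = {r.residue_name for r in records if r.is_hetero and r.residue_name != "HOH"}
        topology = Structure(records, ligand_codes=frozenset(codes))
    coords = np.asarray(stack.coord, dtype=float)
    if coords.shape[1] != len(topology):
        raise FrameCongruenceError(
            f"trajectory frames have {coords.shape[1]} atoms, topology has {len(topology)}"
        )
    return Trajectory(topology=topology, frames=coords, frame_spacing=frame_spacing)


def _records_to_atom_array(structure: Structure) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.coords
    arr.set_annotation("atom_name", np.array([a.name for a in structure.atoms]))
    arr.set_annotation("element", np.array([a.element.upper() for a in structure.atoms]))
    arr.set_annotation("res_name", np.array([a.residue_name for a in structure.atoms]))
    arr.set_annotation("res_id", np.array([a.residue_seq for a in structure.atoms]))
    arr.set_annotation("chain_id", np.array([a.chain for a in structure.atoms]))
    arr.set_annotation("hetero", np.array([a.is_hetero for a in structure.atoms]))
    arr.set_annotation("atom_id", np.array([a.serial for a in structure.atoms]))
    return arr


def write_pdb(structure: Structure, target) -> None:
    """Write a structure as single-model PDB text (coordinates at 3 decimals)."""
    pdb = PDBFile()
    pdb.set_structure(_records_to_atom_array(structure))
    _write_pdbfile(pdb, target)


def write_trajectory(traj: Trajectory, target) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    arr = _records_to_atom_array(traj.topology)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = traj.frames
    pdb = PDBFile()
    pdb.set_structure(stack)
    _write_pdbfile(pdb, target)


def _write_pdbfile(pdb: PDBFile, target) -> None:
    if hasattr(target, "write"):
        pdb.write(target)
    else:
        with open(target, "w") as fh:
            pdb.write(fh)


# ---------------------------------------------------------------------------
# Selection and mutation
# ---------------------------------------------------------------------------


def _atom_mask(structure: Structure, residues=None, names=None, hetero=None,
               chain=None, elements=None) -> np.ndarray:
    mask = np.ones(len(structure), dtype=bool)
    if residues is not None:
        residues = {residues} if isinstance(residues, int) else set(residues)
        mask &= np.array([a.residue_seq in residues for a in structure.atoms])
    if names is not None:
        names = {names} if isinstance(names, str) else set(names)
        mask &= np.array([a.name in names for a in structure.atoms])
    if hetero is not None:
        mask &= np.array([a.is_hetero == hetero for a in structure.atoms])
    if chain is not None:
        mask &= np.array([a.chain == chain for a in structure.atoms])
    if elements is not None:
        elements = {elements} if isinstance(elements, str) else set(elements)
        mask &= np.array([a.element in elements for a in structure.atoms])
    return mask


def select(obj, residues=None, names=None, hetero=None, chain=None, elements=None):
    """Subset a Structure or Trajectory by residue numbers / atom names / hetero flag.

    Atom order is preserved.  An empty selection is permitted but warned about.
    """
    structure = obj.topology if isinstance(obj, Trajectory) else obj
    mask = _atom_mask(structure, residues, names, hetero, chain, elements)
    if not mask.any():
        warnings.warn("selection matched no atoms", stacklevel=2)
    sub_atoms = [a for a, m in zip(structure.atoms, mask) if m]
    sub = Structure(sub_atoms, label=structure.label, ligand_codes=structure.ligand_codes)
    if isinstance(obj, Trajectory):
        return Trajectory(topology=sub, frames=obj.frames[:, mask, :],
                          frame_spacing=obj.frame_spacing)
    return sub


def truncate_to_alanine(structure: Structure, residue: int) -> Structure:
    """Replace one residue's side chain beyond Cβ with nothing — an in-silico
    alanine substitution that keeps the main-chain conformation.

    Keeps N, CA, C, O (and CB when present) of the target residue, renames it
    ALA, and leaves every other atom untouched.  Glycine is a no-op (warned).
    """
    target = [a for a in structure.atoms if a.residue_seq == residue and not a.is_hetero]
    if not target:
        raise ValueError(f"residue {residue} not found")
    res_name = target[0].residue_name
    if res_name not in _STANDARD_AA:
        raise ValueError(f"residue {residue} ({res_name}) is not a standard amino acid")
    if res_name == "GLY":
        warnings.warn(f"residue {residue} is glycine: nothing to truncate", stacklevel=2)
        return structure
    new_atoms = []
    for a in structure.atoms:
        if a.residue_seq == residue and not a.is_hetero:
            if a.name not in _ALA_KEEP:
                continue
            a = replace(a, residue_name="ALA")
        new_atoms.append(a)
    return Structure(new_atoms, label=structure.label, ligand_codes=structure.ligand_codes)
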