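"""Geometric detection of noncovalent contacts: π–π stacking, π–T shape,
hydrogen bonds, halogen bonds; plus aromatic-ring perception.

Rings of the standard aromatic residues (PHE, TYR, TRP, HIS) are taken from
atom-name templates; ligand rings are perceived from a heavy-atom bond graph
(pair distance ≤ 1.6 Å) by minimum cycle basis, keeping 5- and 6-cycles that
are planar to within 0.3 Å — a geometric stand-in for aromaticity, adequate for
idealized and docked poses without connectivity records.

Detection criteria (all configurable, defaults follow common viewer practice):

* π–π stack: ring-centroid distance ≤ 5.5 Å, interplanar angle ≤ 30°,
  lateral offset ≤ 2.5 Å
* π–T shape: centroid distance ≤ 6.0 Å, interplanar angle 60–90°
* hydrogen bond: donor(N/O)–acceptor(N/O) distance ≤ 3.5 Å and, when the donor
  hydrogen is present, D–H···A angle ≥ 120°; without hydrogens the distance
  criterion alone applies
* halogen bond: carbon-bound X ∈ {F, Cl, Br, I} to acceptor O/N/S with
  X···A ≤ 3.5 Å and C–X···A angle ≥ 140°

Interplanar angles are folded to [0°, 90°].  The lateral offset of a ring pair
is the smaller of the two centroid-displacement components perpendicular to
either ring normal, making detection symmetric in its arguments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structio import AtomRecord, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "AromaticRing",
    "InteractionRecord",
    "PiCriteria",
    "HBondCriteria",
    "HalogenCriteria",
    "find_rings",
    "detect_pi",
    "detect_hbonds",
    "detect_halogen_bonds",
    "interaction_profile",
]

# Atom-name templates for the aromatic rings of standard residues.
RING_TEMPLATES: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TYR": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
    "HIS": (("CG", "ND1", "CE1", "NE2", "CD2"),),
}

PLANARITY_TOLERANCE = 0.3  # Å, max deviation from the best-fit plane
BOND_THRESHOLD = 1.6       # Å, heavy-atom pair distance treated as bonded
H_BOND_LENGTH_MAX = 1.3    # Å, covalent X-H distance used to attach hydrogens


@dataclass(frozen=True)
class AromaticRing:
    """A perceived planar 5- or 6-ring with its centroid and unit normal."""

    owner: str                       # e.g. "TRP550" or ligand code "LIG"
    residue_seq: int | None
    member_names: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray
    size: int

    def __post_init__(self):
        c = np.asarray(self.centroid, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        object.__setattr__(self, "centroid", c)
        object.__setattr__(self, "normal", n)
        if self.size not in (5, 6):
            raise ValueError("aromatic rings here have 5 or 6 members")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected noncovalent contact with the geometry that produced it."""

    kind: str                        # hbond | pi_stack | pi_t | halogen
    partner_a: str
    partner_b: str
    residue_seq: int | None          # protein residue involved, if any
    distance: float
    angle: float | None = None
    offset: float | None = None


@dataclass(frozen=True)
class PiCriteria:
    stack_max_distance: float = 5.5
    stack_max_angle: float = 30.0
    stack_max_offset: float = 2.5
    t_max_distance: float = 6.0
    t_min_angle: float = 60.0
    t_max_angle: float = 90.0


@dataclass(frozen=True)
class HBondCriteria:
    max_distance: float = 3.5
    min_angle: float = 120.0
    min_distance: float = 2.0        # excludes covalently bound pairs


@dataclass(frozen=True)
class HalogenCriteria:
    max_distance: float = 3.5
    min_angle: float = 140.0
    halogens: tuple[str, ...] = ("F", "Cl", "Br", "I")
    acceptors: tuple[str, ...] = ("O", "N", "S")


def _plane_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit plane: (centroid, unit normal, max point deviation)."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    normal = vt[2]
    dev = float(np.max(np.abs((points - centroid) @ normal)))
    return centroid, normal, dev


def _ring_from_atoms(owner: str, residue_seq: int | None,
                     atoms: list[AtomRecord]) -> AromaticRing | None:
    points = np.array([a.position for a in atoms])
    centroid, normal, dev = _plane_fit(points)
    if dev > PLANARITY_TOLERANCE:
        return None
    return AromaticRing(
        owner=owner,
        residue_seq=residue_seq,
        member_names=tuple(a.name for a in atoms),
        centroid=centroid,
        normal=normal,
        size=len(atoms),
    )


def _protein_rings(structure: Structure) -> list[AromaticRing]:
    by_res: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for a in structure.atoms:
        if not a.is_hetero and a.residue_name in RING_TEMPLATES:
            by_res.setdefault((a.chain, a.residue_seq, a.residue_name), []).append(a)
    rings = []
    for (chain, seq, name), atoms in by_res.items():
        lookup = {a.name: a for a in atoms}
        for template in RING_TEMPLATES[name]:
            if all(n in lookup for n in template):
                ring = _ring_from_atoms(f"{name}{seq}", seq, [lookup[n] for n in template])
                if ring is not None:
                    rings.append(ring)
    return rings


def _ligand_rings(structure: Structure) -> list[AromaticRing]:
    """Cycle perception over a 1.6 Å heavy-atom bond graph, per hetero residue."""
    by_res: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for a in structure.atoms:
        if a.is_hetero and a.element != "H":
            by_res.setdefault((a.chain, a.residue_seq, a.residue_name), []).append(a)
    rings = []
    for (chain, seq, code), atoms in by_res.items():
        if len(atoms) < 5:
            continue
        coords = np.array([a.position for a in atoms])
        g = nx.Graph()
        g.add_nodes_from(range(len(atoms)))
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        for i, j in zip(*np.where((d > 0) & (d <= BOND_THRESHOLD))):
            if i < j:
                g.add_edge(int(i), int(j))
        for cycle in nx.minimum_cycle_basis(g):
            if len(cycle) not in (5, 6):
                continue
            ordered = _order_cycle(g, cycle)
            if ordered is None:
                continue
            ring = _ring_from_atoms(code, None, [atoms[i] for i in ordered])
            if ring is not None:
                rings.append(ring)
    return rings


def _order_cycle(g: nx.Graph, cycle: list[int]) -> list[int] | None:
    """Walk the cycle's induced subgraph so members are in ring order."""
    sub = g.subgraph(cycle)
    if any(sub.degree(n) < 2 for n in cycle):
        return None
    start = cycle[0]
    ordered = [start]
    prev = None
    current = start
    while True:
        neighbors = [n for n in sub.neighbors(current) if n != prev]
        if not neighbors:
            return None
        nxt = neighbors[0]
        if nxt == start:
            break
        ordered.append(nxt)
        prev, current = current, nxt
        if len(ordered) > len(cycle):
            return None
    return ordered if len(ordered) == len(cycle) else None


def find_rings(structure: Structure) -> list[AromaticRing]:
    """All perceived aromatic rings: protein rings by template, ligand rings by
    cycle perception with a planarity filter."""
    return _protein_rings(structure) + _ligand_rings(structure)


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between ring planes, folded to [0°, 90°]."""
    cosang = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return float(np.degrees(np.arccos(cosang)))


def _lateral_offset(ring_a: AromaticRing, ring_b: AromaticRing) -> float:
    """Smaller of the two perpendicular components of the centroid displacement."""
    sep = ring_b.centroid - ring_a.centroid
    d = np.linalg.norm(sep)
    offs = []
    for normal in (ring_a.normal, ring_b.normal):
        proj = abs(float(np.dot(sep, normal)))
        offs.append(np.sqrt(max(d * d - proj * proj, 0.0)))
    return float(min(offs))


def detect_pi(rings_a, rings_b, criteria: PiCriteria = PiCriteria()) -> list[InteractionRecord]:
    """π–π stacking and π–T-shape records between two ring collections.

    Symmetric in its arguments; each qualifying unordered pair yields one record.
    """
    records = []
    seen = set()
    for ra, rb in itertools.product(rings_a, rings_b):
        if ra is rb:
            continue
        key = frozenset([(ra.owner, ra.member_names), (rb.owner, rb.member_names)])
        if key in seen:
            continue
        seen.add(key)
        dist = float(np.linalg.norm(rb.centroid - ra.centroid))
        angle = _interplanar_angle(ra.normal, rb.normal)
        offset = _lateral_offset(ra, rb)
        kind = None
        if (dist <= criteria.stack_max_distance and angle <= criteria.stack_max_angle
                and offset <= criteria.stack_max_offset):
            kind = "pi_stack"
        elif (dist <= criteria.t_max_distance
              and criteria.t_min_angle <= angle <= criteria.t_max_angle):
            kind = "pi_t"
        if kind:
            records.append(InteractionRecord(
                kind=kind, partner_a=ra.owner, partner_b=rb.owner,
                residue_seq=ra.residue_seq if ra.residue_seq is not None else rb.residue_seq,
                distance=dist, angle=angle, offset=offset,
            ))
    return records


def _attached_hydrogens(structure: Structure, heavy_index: int,
                        coords: np.ndarray) -> list[int]:
    out = []
    heavy = coords[heavy_index]
    for i, a in enumerate(structure.atoms):
        if a.element == "H" and np.linalg.norm(coords[i] - heavy) <= H_BOND_LENGTH_MAX:
            out.append(i)
    return out


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = float(np.clip(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def _partner_label(a: AtomRecord) -> str:
    return f"{a.residue_name}{a.residue_seq}:{a.name}"


def detect_hbonds(structure: Structure, criteria: HBondCriteria = HBondCriteria(),
                  between_hetero_and_protein: bool = False) -> list[InteractionRecord]:
    """Hydrogen bonds between N/O donors and N/O acceptors.

    Donors without an attached hydrogen (common in docked poses) are evaluated
    on the distance criterion alone; a flag is logged once per call.
    """
    coords = structure.coords
    polar = [i for i, a in enumerate(structure.atoms) if a.element in ("N", "O")]
    records = []
    used_distance_only = False
    for i, j in itertools.permutations(polar, 2):
        d_atom, a_atom = structure.atoms[i], structure.atoms[j]
        if d_atom.residue_seq == a_atom.residue_seq and d_atom.is_hetero == a_atom.is_hetero:
            continue
        if between_hetero_and_protein and d_atom.is_hetero == a_atom.is_hetero:
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if not (criteria.min_distance <= dist <= criteria.max_distance):
            continue
        hydrogens = _attached_hydrogens(structure, i, coords)
        angle = None
        if hydrogens:
            angle = max(_angle_deg(coords[i], coords[h], coords[j]) for h in hydrogens)
            if angle < criteria.min_angle:
                continue
        else:
            used_distance_only = True
        # keep one record per unordered pair: donor side is the one with H,
        # otherwise the lower index
        if not hydrogens and i > j:
            continue
        records.append(InteractionRecord(
            kind="hbond", partner_a=_partner_label(d_atom), partner_b=_partner_label(a_atom),
            residue_seq=(a_atom.residue_seq if d_atom.is_hetero else d_atom.residue_seq),
            distance=dist, angle=angle,
        ))
    if used_distance_only:
        logger.info("hydrogen-bond detection fell back to distance-only for "
                    "donors without hydrogens")
    return records


def detect_halogen_bonds(structure: Structure,
                         criteria: HalogenCriteria = HalogenCriteria()
                         ) -> list[InteractionRecord]:
    """Halogen bonds: carbon-bound F/Cl/Br/I to O/N/S acceptors."""
    coords = structure.coords
    records = []
    halogen_idx = [i for i, a in enumerate(structure.atoms)
                   if a.element in criteria.halogens]
    acceptor_idx = [i for i, a in enumerate(structure.atoms)
                    if a.element in criteria.acceptors]
    carbon_idx = [i for i, a in enumerate(structure.atoms) if a.element == "C"]
    for x in halogen_idx:
        # the bound carbon: nearest C within covalent range
        if not carbon_idx:
            continue
        dc = np.linalg.norm(coords[carbon_idx] - coords[x], axis=1)
        nearest = int(np.argmin(dc))
        if dc[nearest] > 2.0:
            continue
        c = carbon_idx[nearest]
        x_atom = structure.atoms[x]
        for aidx in acceptor_idx:
            a_atom = structure.atoms[aidx]
            if a_atom.residue_seq == x_atom.residue_seq and a_atom.is_hetero == x_atom.is_hetero:
                continue
            dist = float(np.linalg.norm(coords[aidx] - coords[x]))
            if dist > criteria.max_distance:
                continue
            angle = _angle_deg(coords[c], coords[x], coords[aidx])
            if angle < criteria.min_angle:
                continue
            records.append(InteractionRecord(
                kind="halogen", partner_a=_partner_label(x_atom),
                partner_b=_partner_label(a_atom),
                residue_seq=(a_atom.residue_seq if x_atom.is_hetero else x_atom.residue_seq),
                distance=dist, angle=angle,
            ))
    return records


def interaction_profile(structure: Structure, ligand_code: str | None = None,
                        pi_criteria: PiCriteria = PiCriteria(),
                        hbond_criteria: HBondCriteria = HBondCriteria(),
                        halogen_criteria: HalogenCriteria = HalogenCriteria()
                        ) -> dict[int, list[InteractionRecord]]:
    """All detected protein–ligand contacts keyed by protein residue number.

    Runs every detector and keeps only records that pair the designated ligand
    with a protein residue.
    """
    codes = {ligand_code} if ligand_code else set(structure.ligand_codes)
    if not codes or not any(a.is_hetero and a.residue_name in codes
                            for a in structure.atoms):
        raise ValueError(f"ligand {sorted(codes)} absent from structure")
    rings = find_rings(structure)
    protein_rings = [r for r in rings if r.residue_seq is not None]
    ligand_rings = [r for r in rings if r.residue_seq is None and r.owner in codes]

    records = detect_pi(protein_rings, ligand_rings, pi_criteria)
    for rec in detect_hbonds(structure, hbond_criteria, between_hetero_and_protein=True):
        records.append(rec)
    for rec in detect_halogen_bonds(structure, halogen_criteria):
        records.append(rec)

    profile: dict[int, list[InteractionRecord]] = {}
    ligand_residues = {a.residue_seq for a in structure.atoms
                       if a.is_hetero and a.residue_name in codes}
    for rec in records:
        if rec.residue_seq is None or rec.residue_seq in ligand_residues:
            continue
        # hbond/halogen records from non-ligand hetero groups are not part of
        # the ligand profile
        if rec.kind in ("hbond", "halogen"):
            partners = (rec.partner_a, rec.partner_b)
            if not any(p.split(":")[0].rstrip("0123456789-") in codes or
                       p.split(":")[0][:3] in codes for p in partners):
                continue
        profile.setdefault(rec.residue_seq, []).append(rec)
    return profile
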