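"""Synthetic kinase-like systems with known ground truth.

Every generator is a pure function of its spec (including the seed), so any
downstream recovery experiment can compare what an analysis reports against
what was planted.  The toy backbone is deliberately non-physical — a smooth
curve with rigid local backbone geometry — because every analysis in the
package is geometric: what must be controlled is the d1/d2 diagnostic
distances, the aromatic site ring, planted ligand poses, planted per-residue
displacements and the coordinate noise, and each of those is realized exactly
(to 1e-6 Å) by construction.

The default toy spans residues 540–800 of the original CSF1R kinase-domain
numbering, so the juxtamembrane tryptophan site (550), the αC glutamate (633),
the HRD aspartate (783), the DFG phenylalanine (797) and the activation-loop
stretch (603–609) all exist.  The default d1/d2 targets are the ligand-free
wild-type window means (7.21, 11.30 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .structio import AtomRecord, Structure, Trajectory, truncate_to_alanine
from .interactions import find_rings

__all__ = [
    "LigandPoseSpec",
    "ToySpec",
    "PlantedShift",
    "TrajectorySpec",
    "CohortSpec",
    "make_toy_kinase",
    "plant_ligand_pose",
    "make_trajectory",
    "make_impact_quartet",
    "make_docking_table",
]

_RING_RADIUS = 1.39  # Å, ideal aromatic C-C ring radius
_MAX_TARGET = 50.0   # Å, beyond this a chain of this size cannot span the gap

# rigid local backbone geometry (offsets from CA, Å)
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.45, 0.00]),
    "C": np.array([1.20, 0.45, 0.00]),
    "O": np.array([1.60, 1.55, 0.00]),
}


@dataclass(frozen=True)
class LigandPoseSpec:
    """A planted aromatic ligand pose relative to the site ring."""

    centroid_distance: float = 3.5   # Å, ring-centroid to ring-centroid
    interplanar_angle: float = 0.0   # degrees
    lateral_offset: float = 0.0      # Å, perpendicular to the site normal
    ligand_code: str = "LIG"


@dataclass(frozen=True)
class ToySpec:
    """A kinase-like toy structure with controllable DFG geometry."""

    n_residues: int = 261
    first_residue: int = 540
    target_d1: float = 7.21
    target_d2: float = 11.30
    aromatic_site: int = 550
    hrd_asp: int = 783
    alphaC_glu: int = 633
    dfg_phe: int = 797
    ligand: LigandPoseSpec | None = None
    seed: int = 0

    def __post_init__(self):
        last = self.first_residue + self.n_residues - 1
        for name in ("aromatic_site", "hrd_asp", "alphaC_glu", "dfg_phe"):
            num = getattr(self, name)
            if not (self.first_residue <= num <= last):
                raise ValueError(f"{name}={num} outside residues "
                                 f"{self.first_residue}..{last}")
        if not (0 < self.target_d1 <= _MAX_TARGET and 0 < self.target_d2 <= _MAX_TARGET):
            raise ValueError("d1/d2 targets must be in (0, 50] Å "
                             "(chain connectivity)")


@dataclass(frozen=True)
class PlantedShift:
    """A radial per-residue displacement planted into a trajectory."""

    residues: tuple[int, ...] = tuple(range(603, 610))
    magnitude: float = 3.0           # Å, outward from the protein center
    applies_to: str = "mutant-only"  # "all" | "WT-only" | "mutant-only"


@dataclass(frozen=True)
class TrajectorySpec:
    base: ToySpec = field(default_factory=ToySpec)
    n_frames: int = 800
    noise_sd: float = 0.3            # Å, isotropic Gaussian per atom per frame
    planted_shift: PlantedShift | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("a trajectory spec needs n_frames >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """A docking-score cohort with a planted contact/affinity association."""

    n_pan: int = 14
    n_specific: int = 15
    score_mean: float = -10.0        # kcal/mol
    score_sd: float = 1.0
    contact_residue: int = 550
    contact_kind: str = "pi_stack"
    contact_effect: float = -1.5     # kcal/mol added to contacting ligands
    contact_probability: dict = field(
        default_factory=lambda: {"pan_tki": 0.4, "csf1r_specific": 0.3})
    seed: int = 0

    def __post_init__(self):
        if self.n_pan < 1 or self.n_specific < 1:
            raise ValueError("each group needs at least one ligand")
        if not all(0.0 <= p <= 1.0 for p in self.contact_probability.values()):
            raise ValueError("contact probabilities must be in [0, 1]")


def _hexagon(centroid: np.ndarray, normal: np.ndarray,
             phase: float = 0.0) -> np.ndarray:
    """Six points of an ideal aromatic hexagon in the plane ⟂ normal."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = phase + np.arange(6) * np.pi / 3
    return centroid + _RING_RADIUS * (
        np.cos(angles)[:, None] * u + np.sin(angles)[:, None] * v)


def make_toy_kinase(spec: ToySpec = ToySpec()) -> Structure:
    """Build the toy kinase: backbone on a smooth helical curve, the three
    diagnostic Cα positions placed so d1/d2 equal the targets to 1e-6 Å, and a
    TRP-like planar 6-ring at the aromatic site.  Deterministic given the spec.
    """
    n = spec.n_residues
    i = np.arange(n)
    t = 0.35 * i
    ca = np.column_stack([12.0 * np.cos(t), 12.0 * np.sin(t), 1.5 * i])

    res_index = {spec.first_residue + k: k for k in range(n)}
    # place the diagnostic triangle: DFG-Phe at an anchor, HRD-Asp at d1 from
    # it, αC-Glu at d2 from it, directions fixed and non-collinear
    anchor = ca.mean(axis=0) + np.array([6.0, 2.0, 0.0])
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([0.30, 0.80, np.sqrt(1 - 0.30 ** 2 - 0.80 ** 2)])
    ca[res_index[spec.dfg_phe]] = anchor
    ca[res_index[spec.hrd_asp]] = anchor + spec.target_d1 * u1
    ca[res_index[spec.alphaC_glu]] = anchor + spec.target_d2 * u2

    atoms: list[AtomRecord] = []
    serial = 1
    for k in range(n):
        seq = spec.first_residue + k
        res_name = "TRP" if seq == spec.aromatic_site else "GLY"
        if seq == spec.hrd_asp:
            res_name = "ASP"
        elif seq == spec.alphaC_glu:
            res_name = "GLU"
        elif seq == spec.dfg_phe:
            res_name = "PHE"
        for name in ("N", "CA", "C", "O"):
            pos = ca[k] + (_BACKBONE_OFFSETS[name] if name != "CA" else 0.0)
            atoms.append(AtomRecord(serial, name, name[0], res_name, seq, "A", pos))
            serial += 1
        if seq == spec.aromatic_site:
            cb = ca[k] + np.array([0.3, -1.3, 0.6])
            atoms.append(AtomRecord(serial, "CB", "C", "TRP", seq, "A", cb))
            serial += 1
            ring_centroid = ca[k] + np.array([0.8, -3.2, 1.4])
            ring_normal = np.array([0.2, 0.1, 1.0])
            ring_normal = ring_normal / np.linalg.norm(ring_normal)
            pts = _hexagon(ring_centroid, ring_normal)
            for name, pos in zip(("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"), pts):
                atoms.append(AtomRecord(serial, name, "C", "TRP", seq, "A", pos))
                serial += 1
    structure = Structure(atoms, label=f"toy-kinase-{spec.seed}")
    if spec.ligand is not None:
        structure = plant_ligand_pose(structure, spec.ligand,
                                      aromatic_site=spec.aromatic_site)
    return structure


def plant_ligand_pose(structure: Structure, pose: LigandPoseSpec,
                      aromatic_site: int | None = None) -> Structure:
    """Attach an ideal hexagonal aromatic ligand at the requested geometry
    relative to the site ring (centroid distance / interplanar angle / lateral
    offset realized to 1e-6 Å)."""
    rings = [r for r in find_rings(structure)
             if r.residue_seq is not None
             and (aromatic_site is None or r.residue_seq == aromatic_site)]
    if not rings:
        raise ValueError(f"no aromatic ring at site {aromatic_site}")
    site = max(rings, key=lambda r: r.size)
    if pose.lateral_offset > pose.centroid_distance:
        raise ValueError("lateral offset cannot exceed the centroid distance")
    along = float(np.sqrt(pose.centroid_distance ** 2 - pose.lateral_offset ** 2))
    # perpendicular direction in the site-ring plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, site.normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(site.normal, ref)
    perp /= np.linalg.norm(perp)
    centroid = site.centroid + along * site.normal + pose.lateral_offset * perp
    # tilt the ligand normal by the interplanar angle about the in-plane axis
    theta = np.radians(pose.interplanar_angle)
    axis = perp
    normal = (np.cos(theta) * site.normal
              + np.sin(theta) * np.cross(axis, site.normal))
    pts = _hexagon(centroid, normal)

    protein_coords = structure.coords
    dmin = np.min(np.linalg.norm(
        protein_coords[None, :, :] - pts[:, None, :], axis=2))
    if dmin < 1.5:
        raise ValueError(f"requested pose collides with protein atoms "
                         f"(min distance {dmin:.2f} Å)")
    serial = max(a.serial for a in structure.atoms) + 1
    lig_atoms = [
        AtomRecord(serial + i, f"C{i + 1}", "C", pose.ligand_code, 1, "L",
                   pos, is_hetero=True)
        for i, pos in enumerate(pts)
    ]
    return Structure(structure.atoms + lig_atoms, label=structure.label,
                     ligand_codes=structure.ligand_codes | {pose.ligand_code})


def _radial_directions(structure: Structure, residues) -> dict[int, np.ndarray]:
    heavy = np.array([a.position for a in structure.atoms
                      if not a.is_hetero and a.element != "H"])
    center = heavy.mean(axis=0)
    out = {}
    for res in residues:
        ca = [a.position for a in structure.atoms
              if a.residue_seq == res and a.name == "CA" and not a.is_hetero]
        if not ca:
            raise ValueError(f"shift residue {res} absent from structure")
        direction = ca[0] - center
        out[res] = direction / np.linalg.norm(direction)
    return out


def _apply_shift(structure: Structure, shift: PlantedShift) -> np.ndarray:
    coords = structure.coords.copy()
    directions = _radial_directions(structure, shift.residues)
    for i, a in enumerate(structure.atoms):
        if not a.is_hetero and a.residue_seq in directions:
            coords[i] += shift.magnitude * directions[a.residue_seq]
    return coords


def make_trajectory(spec: TrajectorySpec, structure: Structure | None = None,
                    apply_shift: bool | None = None
                    ) -> tuple[Trajectory, dict]:
    """Frames = base coordinates (+ planted radial shift) + seeded Gaussian noise.

    ``apply_shift`` overrides the spec's ``applies_to`` bookkeeping for direct
    use; by default the shift is applied when ``applies_to == "all"``.
    Returns the trajectory and a ground-truth record.
    """
    base = structure if structure is not None else make_toy_kinase(spec.base)
    shifted = False
    coords = base.coords
    if spec.planted_shift is not None:
        if apply_shift is None:
            apply_shift = spec.planted_shift.applies_to == "all"
        if apply_shift:
            coords = _apply_shift(base, spec.planted_shift)
            shifted = True
    rng = np.random.default_rng(spec.seed)
    frames = coords[None, :, :] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_frames, len(base), 3))
    truth = {
        "shifted_residues": tuple(spec.planted_shift.residues) if shifted else (),
        "magnitude": spec.planted_shift.magnitude if shifted else 0.0,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return Trajectory(topology=base, frames=frames), truth


def make_impact_quartet(spec: TrajectorySpec) -> tuple[dict[str, Trajectory], dict]:
    """The four trajectories of a mutagenesis impact experiment.

    ``free_wt``, ``bound_wt``, ``free_mut``, ``bound_mut`` share one toy base;
    the mutant pair has the aromatic site truncated to alanine.  The planted
    shift lands in the bound trajectory of the variant(s) named by
    ``applies_to`` — it models a binding-induced conformational change, so
    ΔΔd recovers it when it is mutant-only (or WT-only, with opposite sign).
    """
    if spec.planted_shift is None:
        raise ValueError("an impact quartet needs a planted shift")
    wt = make_toy_kinase(spec.base)
    mut = truncate_to_alanine(wt, spec.base.aromatic_site)
    mut = Structure(mut.atoms, label=wt.label + "-W550A", ligand_codes=mut.ligand_codes)
    applies = spec.planted_shift.applies_to
    seeds = np.random.SeedSequence(spec.seed).generate_state(4)
    # seeds stay below 2**31 for portability
    seeds = [int(s % (2 ** 31)) for s in seeds]
    trajs = {}
    for name, structure, shift in (
        ("free_wt", wt, False),
        ("bound_wt", wt, applies in ("all", "WT-only")),
        ("free_mut", mut, False),
        ("bound_mut", mut, applies in ("all", "mutant-only")),
    ):
        sub = replace(spec, seed=seeds.pop(0))
        traj, _ = make_trajectory(sub, structure=structure, apply_shift=shift)
        trajs[name] = traj
    truth = {
        "shifted_residues": tuple(spec.planted_shift.residues),
        "magnitude": spec.planted_shift.magnitude,
        "applies_to": applies,
        "noise_sd": spec.noise_sd,
        "n_frames": spec.n_frames,
    }
    return trajs, truth


def make_docking_table(spec: CohortSpec = CohortSpec()
                       ) -> tuple[pd.DataFrame, dict]:
    """A seeded docking-score cohort with a planted contact/affinity link.

    Scores are Normal(mean, sd); ligands drawn to contact the chosen residue
    receive ``contact_effect`` added to their score.  Annotations are emitted
    in the ``residue:kind`` dialect.  Returns the table and the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    contact_ann = f"{spec.contact_residue}:{spec.contact_kind}"
    truth_contacts = {}
    for group, count in (("pan_tki", spec.n_pan), ("csf1r_specific", spec.n_specific)):
        p = spec.contact_probability.get(group, 0.0)
        for i in range(count):
            name = f"{group}-{i + 1:02d}"
            contact = bool(rng.random() < p)
            score = float(rng.normal(spec.score_mean, spec.score_sd))
            if contact:
                score += spec.contact_effect
            rows.append({"ligand": name, "group": group, "score": score,
                         "interactions": contact_ann if contact else ""})
            truth_contacts[name] = contact
    df = pd.DataFrame(rows)
    truth = {
        "contacts": truth_contacts,
        "contact_effect": spec.contact_effect,
        "contact_residue": spec.contact_residue,
        "contact_kind": spec.contact_kind,
        "seed": spec.seed,
    }
    return df, truth
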