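"""Per-residue distance-from-protein-center profiles and conformational-impact calls.

The central procedure: for every protein residue, track the distance of its
backbone point from the protein center over a trajectory window.  The change in
these profiles upon ligand binding (Δd = bound − free, negative meaning the
residue moved toward the center) is computed separately for the wild type (Δd₁)
and a mutant (Δd₂); their difference ΔΔd = Δd₂ − Δd₁ is thresholded to call
which residues the mutation affects: |ΔΔd| > 1.5 Å a *slight* conformational
change, |ΔΔd| > 2.0 Å a *significant* one (strict inequalities; exactly 2.0 Å
is still "slight").  The thresholds sit between the length of a hydrogen bond
(~2 Å) and a hydrophobic contact (~4 Å) — the scale on which a residue can gain
or lose an interaction.

The protein center excludes hetero atoms and hydrogens and is mass-weighted by
default.  The residue point is the geometric centroid of the backbone atoms
N, CA, C, O ("backbone" rule) or the α-carbon alone ("CA" rule).  The default
window is the last 40% of frames (equilibrated tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import BACKBONE_NAMES, SeriesResult, atomic_masses
from .structio import Structure, Trajectory

__all__ = [
    "DistanceProfile",
    "DeltaProfile",
    "ImpactCall",
    "SLIGHT_THRESHOLD",
    "SIGNIFICANT_THRESHOLD",
    "default_window",
    "residue_center_distances",
    "average_profiles",
    "delta_profile",
    "impact_call",
    "ligand_center_series",
]

SLIGHT_THRESHOLD = 1.5  # Å
SIGNIFICANT_THRESHOLD = 2.0  # Å

DEFAULT_WINDOW_FRACTION = 0.4  # last 40% of frames (e.g. 800 of 2000)


def default_window(n_frames: int, fraction: float = DEFAULT_WINDOW_FRACTION) -> slice:
    """The equilibrated-tail window: the last ``fraction`` of the frames."""
    start = n_frames - max(1, int(round(n_frames * fraction)))
    return slice(start, n_frames)


@dataclass
class DistanceProfile:
    """Mean ± SD distance of each residue's point from the protein center, Å."""

    residues: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    window: tuple[int, int]
    center_rule: str
    residue_point_rule: str
    label: str = ""

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.residues) == len(self.mean) == len(self.sd)):
            raise ValueError("profile arrays must have equal length")
        if np.any(self.mean < 0) or np.any(self.sd < 0):
            raise ValueError("distances and spreads must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "mean": self.mean, "sd": self.sd})

    def to_csv(self, target) -> None:
        self.to_frame().to_csv(target, index=False)


@dataclass
class DeltaProfile:
    """Signed per-residue Δd (bound − free); negative = moved toward the center."""

    residues: np.ndarray
    dd: np.ndarray
    provenance: tuple[str, str] = ("bound", "free")
    symbol: str = "dd"

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=int)
        self.dd = np.asarray(self.dd, dtype=float)
        if len(self.residues) != len(self.dd):
            raise ValueError("delta profile arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "delta_d": self.dd})


@dataclass
class ImpactCall:
    """Per-residue ΔΔd with the unaffected / slight / significant label."""

    residues: np.ndarray
    ddd: np.ndarray
    labels: np.ndarray
    slight_threshold: float = SLIGHT_THRESHOLD
    significant_threshold: float = SIGNIFICANT_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residues, "delta_delta_d": self.ddd, "label": self.labels}
        )

    def to_csv(self, target) -> None:
        self.to_frame().to_csv(target, index=False)

    def affected(self) -> np.ndarray:
        return self.residues[self.labels != "unaffected"]

    def significant(self) -> np.ndarray:
        return self.residues[self.labels == "significant"]


def _protein_center_mask(structure: Structure) -> np.ndarray:
    return np.array(
        [not a.is_hetero and a.element != "H" for a in structure.atoms], dtype=bool
    )


def _residue_point_groups(structure: Structure, rule: str):
    """(residue numbers, list of atom-index arrays) for the residue-point rule."""
    wanted = ("CA",) if rule == "CA" else BACKBONE_NAMES
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if not a.is_hetero and a.name in wanted:
            groups.setdefault(a.residue_seq, []).append(i)
    residues = np.array(sorted(groups), dtype=int)
    return residues, [np.array(groups[r], dtype=int) for r in residues]


def residue_center_distances(traj: Trajectory, window: slice | None = None,
                             center_rule: str = "mass",
                             residue_point_rule: str = "backbone") -> DistanceProfile:
    """Per-residue mean ± SD distance from the protein center over a frame window.

    The center is recomputed per frame from protein heavy atoms only.
    """
    if residue_point_rule not in ("backbone", "CA"):
        raise ValueError(f"unknown residue point rule {residue_point_rule!r}")
    window = window if window is not None else default_window(traj.n_frames)
    frames = traj.frames[window]
    if frames.shape[0] == 0:
        raise ValueError("empty frame window")
    center_mask = _protein_center_mask(traj.topology)
    if not center_mask.any():
        raise ValueError("no protein heavy atoms to define a center")
    if center_rule == "mass":
        w = atomic_masses([a.element for a, m in zip(traj.topology.atoms, center_mask) if m])
    elif center_rule == "geometric":
        w = np.ones(int(center_mask.sum()))
    else:
        raise ValueError(f"unknown center rule {center_rule!r}")
    centers = np.einsum("fij,i->fj", frames[:, center_mask, :], w) / w.sum()

    residues, groups = _residue_point_groups(traj.topology, residue_point_rule)
    n_f, n_r = frames.shape[0], len(residues)
    dist = np.empty((n_f, n_r))
    for j, idx in enumerate(groups):
        pts = frames[:, idx, :].mean(axis=1)
        dist[:, j] = np.linalg.norm(pts - centers, axis=1)
    start, stop, _ = window.indices(traj.n_frames)
    return DistanceProfile(
        residues=residues,
        mean=dist.mean(axis=0),
        sd=dist.std(axis=0, ddof=0),
        window=(start, stop),
        center_rule=center_rule,
        residue_point_rule=residue_point_rule,
        label=traj.topology.label,
    )


def average_profiles(profiles: list[DistanceProfile],
                     label: str = "") -> DistanceProfile:
    """Average replicate profiles (equal windows) as if their frame windows had
    been concatenated: the mean is the mean of means, the variance pools the
    within-replicate variances with the between-replicate spread of means."""
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residues, first.residues):
            raise ValueError("replicate profiles cover different residues")
        if p.center_rule != first.center_rule or \
                p.residue_point_rule != first.residue_point_rule:
            raise ValueError("replicate profiles use different rules")
    means = np.stack([p.mean for p in profiles])
    sds = np.stack([p.sd for p in profiles])
    mean = means.mean(axis=0)
    var = (sds ** 2).mean(axis=0) + means.var(axis=0, ddof=0)
    return DistanceProfile(
        residues=first.residues, mean=mean, sd=np.sqrt(var),
        window=first.window, center_rule=first.center_rule,
        residue_point_rule=first.residue_point_rule,
        label=label or first.label,
    )


def delta_profile(bound: DistanceProfile, free: DistanceProfile,
                  symbol: str = "dd") -> DeltaProfile:
    """Δd(residue) = bound.mean − free.mean on the residue intersection.

    Negative values mean the residue moved closer to the protein center upon
    binding.
    """
    if bound.center_rule != free.center_rule or \
            bound.residue_point_rule != free.residue_point_rule:
        raise ValueError("profiles computed under different center/point rules")
    common, i_b, i_f = np.intersect1d(bound.residues, free.residues,
                                      return_indices=True)
    if common.size == 0:
        raise ValueError("profiles share no residues")
    return DeltaProfile(
        residues=common,
        dd=bound.mean[i_b] - free.mean[i_f],
        provenance=(bound.label, free.label),
        symbol=symbol,
    )


def impact_call(d1: DeltaProfile, d2: DeltaProfile,
                slight_threshold: float = SLIGHT_THRESHOLD,
                significant_threshold: float = SIGNIFICANT_THRESHOLD) -> ImpactCall:
    """ΔΔd = Δd₂ (mutant) − Δd₁ (wild type), labelled per residue.

    unaffected if |ΔΔd| ≤ slight, slight if slight < |ΔΔd| ≤ significant,
    significant if |ΔΔd| > significant (both boundaries strict ">").
    """
    if significant_threshold < slight_threshold:
        raise ValueError("significant threshold must be >= slight threshold")
    common, i1, i2 = np.intersect1d(d1.residues, d2.residues, return_indices=True)
    if common.size == 0:
        raise ValueError("delta profiles share no residues")
    ddd = d2.dd[i2] - d1.dd[i1]
    mag = np.abs(ddd)
    labels = np.where(
        mag > significant_threshold, "significant",
        np.where(mag > slight_threshold, "slight", "unaffected"),
    )
    return ImpactCall(common, ddd, labels, slight_threshold, significant_threshold)


def ligand_center_series(traj: Trajectory, ligand_code: str) -> SeriesResult:
    """Per-frame distance between the ligand and protein centers of mass, Å."""
    lig_mask = np.array(
        [a.is_hetero and a.residue_name == ligand_code for a in traj.topology.atoms]
    )
    if not lig_mask.any():
        raise ValueError(f"ligand code {ligand_code!r} absent from topology")
    prot_mask = _protein_center_mask(traj.topology)
    atoms = traj.topology.atoms
    w_lig = atomic_masses([a.element for a, m in zip(atoms, lig_mask) if m])
    w_prot = atomic_masses([a.element for a, m in zip(atoms, prot_mask) if m])
    lig_com = np.einsum("fij,i->fj", traj.frames[:, lig_mask, :], w_lig) / w_lig.sum()
    prot_com = np.einsum("fij,i->fj", traj.frames[:, prot_mask, :], w_prot) / w_prot.sum()
    values = np.linalg.norm(lig_com - prot_com, axis=1)
    return SeriesResult(values, np.arange(traj.n_frames), "distance")
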