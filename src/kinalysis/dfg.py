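"""Kinase conformational-state classification from two diagnostic Cα distances.

Protein kinases toggle between an active (DFG-in) and inactive (DFG-out)
conformation of the conserved Asp-Phe-Gly motif at the start of the activation
loop.  Two α-carbon distances diagnose the state:

* d1 — from the HRD-motif aspartate (CSF1R D783) to the DFG phenylalanine (F797)
* d2 — from the conserved αC-helix glutamate (E633) to the DFG phenylalanine

The kinase is called inactive (DFG-out) when d1 < d2 and active (DFG-in) when
d1 > d2; exact equality is reported as "boundary" rather than guessed.  Within
the inactive state the *classical* DFG-out geometry — the one type-II inhibitors
such as imatinib occupy — satisfies d1 < 7.2 Å and d2 > 9.0 Å (strict); an
inactive call failing either bound is a *nonclassical* DFG-out.  Independently,
d2 > 10.5 Å flags an outward-rotated αC-helix (αC-out).  The αC-out flag is an
annotation alongside the DFG class, not a replacement for it: a classical
DFG-out structure can simultaneously be αC-out.

Classification operates on window-mean distances (as tabulated from MD), not on
a per-frame majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import ResidueMap, Structure, Trajectory, select

__all__ = [
    "DfgResidues",
    "DfgDistances",
    "KinaseStateCall",
    "StateThresholds",
    "dfg_distances",
    "classify_state",
    "batch_classify",
]


@dataclass(frozen=True)
class DfgResidues:
    """Original-numbering residues defining d1 and d2 (CSF1R defaults)."""

    hrd_asp: int = 783
    alphaC_glu: int = 633
    dfg_phe: int = 797


@dataclass(frozen=True)
class StateThresholds:
    """Distance cut-offs in Å for the classical DFG-out and αC-out calls."""

    t_d1: float = 7.2
    t_d2: float = 9.0
    t_alphaC: float = 10.5


@dataclass
class DfgDistances:
    d1: float
    d2: float
    sd1: float = 0.0
    sd2: float = 0.0
    label: str = ""
    window: tuple[int, int] | None = None

    def __post_init__(self):
        if not (self.d1 > 0 and self.d2 > 0):
            raise ValueError("d1 and d2 must be positive")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SDs must be non-negative")


@dataclass
class KinaseStateCall:
    activity: str            # "inactive" | "active" | "boundary"
    dfg_class: str           # "classical_out" | "nonclassical_out" | "in" | "n/a"
    alphaC_out: bool
    distances: DfgDistances
    thresholds: StateThresholds = field(default_factory=StateThresholds)


def _ca_position(structure: Structure, residue: int) -> np.ndarray:
    for a in structure.atoms:
        if a.residue_seq == residue and a.name == "CA" and not a.is_hetero:
            return a.position
    raise ValueError(f"residue {residue} has no CA atom")


def dfg_distances(obj, residue_map: ResidueMap | None = None,
                  residues: DfgResidues = DfgResidues(),
                  window: slice | None = None, label: str = "") -> DfgDistances:
    """Compute d1 (HRD-Asp Cα ↔ DFG-Phe Cα) and d2 (αC-Glu Cα ↔ DFG-Phe Cα).

    ``obj`` is a Structure (single conformation) or a Trajectory, in which case
    the distances are averaged (mean ± SD) over the frame ``window`` (all frames
    by default).  Residue numbers are original-scheme; pass a ``residue_map``
    when the coordinates use rearranged numbering.
    """
    rmap = residue_map or ResidueMap.identity()
    nums = {k: rmap.to_rearranged(v) if residue_map else v
            for k, v in (("hrd_asp", residues.hrd_asp),
                         ("alphaC_glu", residues.alphaC_glu),
                         ("dfg_phe", residues.dfg_phe))}
    if isinstance(obj, Structure):
        asp = _ca_position(obj, nums["hrd_asp"])
        glu = _ca_position(obj, nums["alphaC_glu"])
        phe = _ca_position(obj, nums["dfg_phe"])
        return DfgDistances(
            d1=float(np.linalg.norm(asp - phe)),
            d2=float(np.linalg.norm(glu - phe)),
            label=label or obj.label,
        )
    traj: Trajectory = obj
    idx = {}
    for key, num in nums.items():
        matches = [i for i, a in enumerate(traj.topology.atoms)
                   if a.residue_seq == num and a.name == "CA" and not a.is_hetero]
        if not matches:
            raise ValueError(f"residue {num} ({key}) has no CA atom")
        idx[key] = matches[0]
    window = window if window is not None else slice(None)
    frames = traj.frames[window]
    d1 = np.linalg.norm(frames[:, idx["hrd_asp"]] - frames[:, idx["dfg_phe"]], axis=1)
    d2 = np.linalg.norm(frames[:, idx["alphaC_glu"]] - frames[:, idx["dfg_phe"]], axis=1)
    start, stop, _ = window.indices(traj.n_frames)
    return DfgDistances(
        d1=float(d1.mean()), d2=float(d2.mean()),
        sd1=float(d1.std(ddof=0)), sd2=float(d2.std(ddof=0)),
        label=label or traj.topology.label, window=(start, stop),
    )


def classify_state(d: DfgDistances,
                   thresholds: StateThresholds = StateThresholds()) -> KinaseStateCall:
    """Activity from d1 vs d2 (strict; tie -> boundary); classical vs nonclassical
    DFG-out from the (7.2, 9.0) Å cut-offs; αC-out annotated when d2 > 10.5 Å."""
    if d.d1 < d.d2:
        activity = "inactive"
        if d.d1 < thresholds.t_d1 and d.d2 > thresholds.t_d2:
            dfg_class = "classical_out"
        else:
            dfg_class = "nonclassical_out"
    elif d.d1 > d.d2:
        activity, dfg_class = "active", "in"
    else:
        activity, dfg_class = "boundary", "n/a"
    return KinaseStateCall(
        activity=activity,
        dfg_class=dfg_class,
        alphaC_out=bool(d.d2 > thresholds.t_alphaC),
        distances=d,
        thresholds=thresholds,
    )


def batch_classify(table: pd.DataFrame,
                   thresholds: StateThresholds = StateThresholds()
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every row of a (label, d1, d2[, sd1, sd2]) table.

    Returns the table with appended ``activity``, ``dfg_class`` and ``alphaC_out``
    columns plus a summary count of each activity and DFG class.
    """
    out = table.copy()
    calls = []
    for _, row in table.iterrows():
        d = DfgDistances(
            d1=float(row["d1"]), d2=float(row["d2"]),
            sd1=float(row.get("sd1", 0.0) or 0.0), sd2=float(row.get("sd2", 0.0) or 0.0),
            label=str(row.get("label", "")),
        )
        calls.append(classify_state(d, thresholds))
    out["activity"] = [c.activity for c in calls]
    out["dfg_class"] = [c.dfg_class for c in calls]
    out["alphaC_out"] = [c.alphaC_out for c in calls]
    counts: dict[str, int] = {}
    for key in ("inactive", "active", "boundary"):
        counts[key] = int((out["activity"] == key).sum()) if len(out) else 0
    for key in ("classical_out", "nonclassical_out", "in", "n/a"):
        counts[key] = int((out["dfg_class"] == key).sum()) if len(out) else 0
    counts["alphaC_out"] = int(out["alphaC_out"].sum()) if len(out) else 0
    return out, counts
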