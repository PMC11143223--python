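"""Rigid-body superposition and standard trajectory summaries (RMSD, RMSF, Rg).

Conventions: RMSD defaults to backbone atoms (N, CA, C, O) least-squares fitted
to the first frame; RMSF aligns frames to the window-mean structure with a single
alignment pass.  Masses are standard atomic masses by element; an unknown element
falls back to unit mass with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure.info as _info

from .structio import Structure, Trajectory, select

__all__ = [
    "RigidTransform",
    "SeriesResult",
    "atomic_masses",
    "center_of_mass",
    "superpose",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SeriesResult:
    """An indexed series of non-negative values in Å (RMSD, RMSF, Rg, distances)."""

    values: np.ndarray
    index: np.ndarray
    statistic_name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.index = np.asarray(self.index)
        if self.values.shape != self.index.shape:
            raise ValueError("values and index length mismatch")
        if np.any(self.values < -1e-12):
            raise ValueError(f"{self.statistic_name} values must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"index": self.index, self.statistic_name: self.values})

    def to_csv(self, target) -> None:
        self.to_frame().to_csv(target, index=False)


def _mass_of(element: str) -> float:
    try:
        m = _info.mass(element.capitalize())
        if m is not None:
            return float(m)
    except KeyError:
        pass
    warnings.warn(f"unknown element {element!r}: using unit mass", stacklevel=3)
    return 1.0


def atomic_masses(elements) -> np.ndarray:
    return np.array([_mass_of(e) for e in elements], dtype=float)


def _weights(obj, coords: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "geometric":
        return np.ones(len(coords))
    if weighting == "mass":
        if isinstance(obj, Structure):
            return atomic_masses(obj.elements)
        raise ValueError("mass weighting requires a Structure with elements")
    raise ValueError(f"unknown weighting {weighting!r}")


def center_of_mass(obj, weighting: str = "mass") -> np.ndarray:
    """Weighted mean position of a Structure (or a bare coordinate array with
    ``weighting='geometric'``)."""
    coords = obj.coords if isinstance(obj, Structure) else np.asarray(obj, float)
    if coords.size == 0:
        raise ValueError("cannot take the center of an empty selection")
    w = _weights(obj, coords, weighting)
    return (w[:, None] * coords).sum(axis=0) / w.sum()


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``
    (Kabsch), returning the transform and the post-fit RMSD in Å."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("point sets must have equal shape")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        weights = np.ones(n)
    wsum = weights.sum()
    cm = (weights[:, None] * mobile).sum(0) / wsum
    cr = (weights[:, None] * reference).sum(0) / wsum
    mob_c = mobile - cm
    ref_c = reference - cr
    if min(np.linalg.matrix_rank(mob_c, tol=1e-9),
           np.linalg.matrix_rank(ref_c, tol=1e-9)) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c, weights=weights)
    R = rot.as_matrix()
    t = cr - R @ cm
    rmsd_after = float(rssd / np.sqrt(wsum))
    return RigidTransform(R, t), rmsd_after


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _selection_mask(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return np.array([a.name in BACKBONE_NAMES and not a.is_hetero
                         for a in traj.topology.atoms])
    if isinstance(selection, np.ndarray) and selection.dtype == bool:
        return selection
    # dict of select() keyword arguments
    from .structio import _atom_mask

    return _atom_mask(traj.topology, **selection)


def rmsd_series(traj: Trajectory, reference: np.ndarray | None = None,
                selection=None, fit: bool = True) -> SeriesResult:
    """Per-frame RMSD of the selected atoms against a reference frame.

    ``selection`` defaults to the protein backbone (N, CA, C, O); ``reference``
    defaults to the selected atoms of the first frame.  With ``fit=True`` each
    frame is least-squares superposed on the reference first.
    """
    mask = _selection_mask(traj, selection)
    if not mask.any():
        raise ValueError("empty selection for RMSD")
    sel = traj.frames[:, mask, :]
    ref = sel[0] if reference is None else np.asarray(reference, float)
    if ref.shape != sel[0].shape:
        raise ValueError("reference incongruent with selection")
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(sel):
        if fit:
            _, values[i] = superpose(frame, ref)
        else:
            values[i] = _rmsd(frame, ref)
    return SeriesResult(values, np.arange(traj.n_frames), "rmsd")


def rmsf(traj: Trajectory, selection=None, window: slice | None = None,
         fit: bool = True) -> SeriesResult:
    """Per-atom root-mean-square fluctuation about the window-mean position.

    Frames are aligned to the window-mean structure with one alignment pass
    (mean of raw frames -> align -> re-mean) when ``fit=True``.
    """
    mask = _selection_mask(traj, selection)
    if not mask.any():
        raise ValueError("empty selection for RMSF")
    window = window or slice(None)
    sel = traj.frames[window, :, :][:, mask, :]
    if sel.shape[0] < 2:
        raise ValueError("RMSF needs a window of at least 2 frames")
    if fit:
        mean0 = sel.mean(axis=0)
        aligned = np.empty_like(sel)
        for i, frame in enumerate(sel):
            tf, _ = superpose(frame, mean0)
            aligned[i] = tf.apply(frame)
        sel = aligned
    mean = sel.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((sel - mean) ** 2, axis=2), axis=0))
    atoms = [a for a, m in zip(traj.topology.atoms, mask) if m]
    index = np.array([a.residue_seq for a in atoms])
    return SeriesResult(fluct, index, "rmsf")


def radius_of_gyration(obj, weighting: str = "mass") -> float:
    """Mass-weighted RMS distance of the atoms from their center of mass, Å."""
    coords = obj.coords if isinstance(obj, Structure) else np.asarray(obj, float)
    if coords.size == 0:
        raise ValueError("cannot compute Rg of an empty selection")
    w = _weights(obj, coords, weighting)
    com = (w[:, None] * coords).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((coords - com) ** 2, axis=1)).sum() / w.sum()))
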