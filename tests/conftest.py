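import numpy as np
import pytest

from kinalysis.structio import AtomRecord, Structure, Trajectory


def make_structure(positions, names=None, residues=None, elements=None,
                   res_names=None, hetero=None, label="test"):
    """Small helper to build a Structure from bare arrays."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    names = names or ["CA"] * n
    residues = residues if residues is not None else list(range(1, n + 1))
    elements = elements or [nm[0] for nm in names]
    res_names = res_names or ["GLY"] * n
    hetero = hetero or [False] * n
    atoms = [
        AtomRecord(i + 1, names[i], elements[i], res_names[i], residues[i],
                   "A", positions[i], is_hetero=hetero[i])
        for i in range(n)
    ]
    return Structure(atoms, label=label)


@pytest.fixture
def three_residue_structure():
    """Three GLY residues with full backbones on a line, 4 Å apart."""
    atoms = []
    serial = 1
    for res in range(1, 4):
        base = np.array([4.0 * res, 0.0, 0.0])
        for name, off in (("N", [-1.2, 0.4, 0]), ("CA", [0, 0, 0]),
                          ("C", [1.2, 0.4, 0]), ("O", [1.6, 1.5, 0])):
            atoms.append(AtomRecord(serial, name, name[0], "GLY", res, "A",
                                    base + np.array(off)))
            serial += 1
    return Structure(atoms, label="tripeptide")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def frozen_trajectory(structure, n_frames):
    coords = structure.coords
    return Trajectory(topology=structure,
                      frames=np.repeat(coords[None], n_frames, axis=0))
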