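import numpy as np
import pytest

from saltscan.sequence_io import SeqRecord
from saltscan.substitution_scan import AlignmentMatrix, LabeledSequencePanel
from saltscan.trajectory_metrics import AtomRecord, Trajectory


@pytest.fixture
def toy_panel():
    """Five-sequence panel with one strict D/H site (col 6), one A/P
    confounded site (col 4), and a monomorphic background."""
    rows = {
        "tol1": "MKVAEDGW",
        "tol2": "MKVPEDGW",
        "sen1": "MKVAEHGW",
        "sen2": "MKVPEHGW",
        "sen3": "MKVAEHGW",
    }
    labels = {"tol1": "tolerant", "tol2": "tolerant", "sen1": "sensitive", "sen2": "sensitive", "sen3": "sensitive"}
    records = tuple(SeqRecord(id=k, residues=v, alphabet="protein") for k, v in rows.items())
    panel = LabeledSequencePanel(records=records, labels=labels)
    aln = AlignmentMatrix(list(rows), list(rows.values()))
    return panel, aln


def two_atom_trajectory(distances):
    """One single-heavy-atom residue pair, one frame per requested distance."""
    atoms = [
        AtomRecord(residue_index=1, residue_name="ALA", atom_name="CB", element="C"),
        AtomRecord(residue_index=2, residue_name="ALA", atom_name="CB", element="C"),
    ]
    frames = [np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]) for d in distances]
    return Trajectory(atoms, frames)


@pytest.fixture
def pair_trajectory_factory():
    return two_atom_trajectory


def random_trajectory(rng, n_res=5, atoms_per_res=3, n_frames=20, box=8.0):
    """Dense random system used by brute-force comparison tests."""
    atoms = []
    for r in range(1, n_res + 1):
        for a in range(atoms_per_res):
            atoms.append(
                AtomRecord(residue_index=r, residue_name="ALA", atom_name=f"C{a}" if a else "CA", element="C")
            )
    frames = [rng.uniform(0, box, size=(len(atoms), 3)) for _ in range(n_frames)]
    return Trajectory(atoms, frames)


@pytest.fixture
def random_trajectory_factory():
    return random_trajectory
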