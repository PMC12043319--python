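import numpy as np
import pytest

from mwsumd.structures import AtomSelection, Topology, Trajectory, WalkerState


@pytest.fixture
def tri_pdb(tmp_path):
    """Three-atom PDB fixture at (0,0,0), (1,0,0), (0,1,0)."""
    lines = [
        "REMARK  toy fixture",
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C",
        "ATOM      3  C   ALA A   1       0.000   1.000   0.000  1.00  0.00           C",
        "END",
    ]
    path = tmp_path / "tri.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def chain_topology():
    """300 'residues', each with CA and CB pseudo-atoms."""
    n_res = 300
    names, res_ids = [], []
    for r in range(1, n_res + 1):
        names += ["CA", "CB"]
        res_ids += [r, r]
    n = len(names)
    return Topology(
        atom_names=names,
        elements=["C"] * n,
        residue_names=["ALA"] * n,
        residue_ids=np.array(res_ids),
        chain_ids=["A"] * n,
        masses=np.full(n, 12.011),
    )


def make_trajectory(coord_frames, dt=1.0, t0=0.0):
    frames = [
        WalkerState(np.asarray(c, float), time=t0 + i * dt)
        for i, c in enumerate(coord_frames)
    ]
    return Trajectory(frames, frame_interval=dt)


@pytest.fixture
def pair_selections():
    return AtomSelection(np.array([0]), "a"), AtomSelection(np.array([1]), "b")
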