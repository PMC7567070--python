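import numpy as np
import pytest

from trajmetrics import (
    Atom,
    FluctuationSpec,
    HelixSpec,
    Structure,
    Trajectory,
    build_ideal_helix,
    simulate_fluctuations,
)

TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
END
"""

MULTI_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.500   3.000   3.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       1.100   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.600   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.600   3.000   3.000  1.00  0.00           C
ENDMDL
MODEL        3
ATOM      1  N   ALA A   1       1.200   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.700   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.700   3.000   3.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.000   1.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def two_atom_pdb(tmp_path):
    p = tmp_path / "two_atom.pdb"
    p.write_text(TWO_ATOM_PDB)
    return p


@pytest.fixture
def multi_model_pdb(tmp_path):
    p = tmp_path / "multi_model.pdb"
    p.write_text(MULTI_MODEL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def make_atoms(n, name="CA", element="C", mass=12.011, resid_start=1):
    return [
        Atom(
            serial=i + 1,
            name=name,
            element=element,
            residue_name="ALA",
            residue_seq=resid_start + i,
            chain_id="A",
            mass=mass,
        )
        for i in range(n)
    ]


@pytest.fixture
def equal_mass_atoms():
    return make_atoms(4)


@pytest.fixture
def helix_residue_table():
    """A 5-residue helix-like atom table with N, CA, C, O (+ one CB)."""
    atoms = []
    serial = 1
    for resid in range(1, 6):
        names = ["N", "CA", "C", "O"] + (["CB"] if resid == 3 else [])
        for name in names:
            element = name[0]
            mass = {"N": 14.007, "C": 12.011, "O": 15.999}[element]
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name="ALA",
                    residue_seq=resid,
                    chain_id="A",
                    mass=mass,
                )
            )
            serial += 1
    return atoms


@pytest.fixture
def jitter_trajectory():
    """10^4-frame isotropic 0.5 A jitter around a helix (no drift)."""
    base = build_ideal_helix(HelixSpec(n_residues=6))
    return simulate_fluctuations(
        base, FluctuationSpec(sigma=0.5, n_frames=10_000, dt=1.0, seed=2024)
    )


def trajectory_from_frames(frames, atoms=None, times=None):
    frames = np.asarray(frames, dtype=float)
    if atoms is None:
        atoms = make_atoms(frames.shape[1])
    if times is None:
        times = np.arange(frames.shape[0], dtype=float)
    return Trajectory(atoms=atoms, frames=frames, times=times)


def structure_from_coords(coords, atoms=None):
    coords = np.asarray(coords, dtype=float)
    if atoms is None:
        atoms = make_atoms(coords.shape[0])
    return Structure(atoms=atoms, coords=coords)
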