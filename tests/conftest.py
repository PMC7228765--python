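import numpy as np
import pandas as pd
import pytest

from domainlink.trajectory_io import Trajectory


def make_atoms(n_residues: int, atom_names=("CA",), chain="A") -> pd.DataFrame:
    """Atom table with the given atoms for each of n consecutive residues."""
    rows = [
        (res, "ALA", name, chain)
        for res in range(1, n_residues + 1)
        for name in atom_names
    ]
    return pd.DataFrame(
        rows, columns=["residue_number", "residue_name", "atom_name", "chain_id"]
    )


def make_trajectory(coords: np.ndarray, atom_names=("CA",)) -> Trajectory:
    """Trajectory whose atom table matches the coordinate array shape."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    per_res = len(atom_names)
    assert n_atoms % per_res == 0
    return Trajectory(coords, make_atoms(n_atoms // per_res, atom_names))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_trajectory(rng):
    """20 frames of 12 CA atoms with small random displacements."""
    base = rng.uniform(-10, 10, size=(12, 3))
    coords = base[None] + rng.normal(scale=0.5, size=(20, 12, 3))
    return make_trajectory(coords)
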