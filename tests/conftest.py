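import numpy as np
import pandas as pd
import pytest

from branchkit.io import ATOM_COLUMNS, AtomTable, BranchModel
from branchkit.synthetic import make_toy_monomer, standard_branch


def atoms_from_xyz(
    xyz, atom_name="CA", chain="A", element="C", start_residue=1, residue_names=None
) -> AtomTable:
    """Build an AtomTable from bare coordinates, one residue per atom."""
    xyz = np.asarray(xyz, float)
    rows = [
        (
            chain,
            start_residue + i,
            "",
            (residue_names[i] if residue_names else "ALA"),
            atom_name,
            element,
            *xyz[i],
            1.0,
            "",
            True,
        )
        for i in range(len(xyz))
    ]
    return AtomTable(pd.DataFrame(rows, columns=ATOM_COLUMNS))


def random_model(rng, labels, n_residues=40, spread=30.0) -> BranchModel:
    """Random labelled subunits: clouds of Calpha atoms in a common box."""
    subs = {}
    for label in labels:
        center = rng.uniform(-spread, spread, 3)
        xyz = center + rng.normal(scale=8.0, size=(n_residues, 3))
        subs[label] = atoms_from_xyz(xyz)
    return BranchModel(subs, provenance="random")


@pytest.fixture(scope="session")
def branch_with_truth():
    """Canonical 18-subunit synthetic branch (8 mother + 3 daughter + 7 complex)."""
    return standard_branch(theta=71.0, seed=1)


@pytest.fixture(scope="session")
def monomer():
    return make_toy_monomer(50, 14.0, seed=7)
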