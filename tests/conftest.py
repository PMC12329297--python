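import numpy as np
import pytest

from afrestraints import FixtureSpec, StructureModel, generate_structure
from afrestraints.structure_io import AtomRecord


@pytest.fixture
def linear_chain_10():
    """10 collinear Cα spaced 4 Å, uniform pLDDT 85."""
    return generate_structure(
        FixtureSpec(n_residues=10, geometry="linear", spacing=4.0, plddt_profile=85.0)
    )


@pytest.fixture
def helix_18():
    return generate_structure(FixtureSpec(n_residues=18, geometry="helix"))


@pytest.fixture
def two_level_63():
    """63 residues mimicking a prediction where 44 residues score 85 and
    the remaining 19 score 75."""
    return generate_structure(
        FixtureSpec(
            n_residues=63,
            geometry="helix",
            plddt_profile=("two_level", 44, 85.0, 75.0),
        )
    )


def random_structure(rng: np.random.Generator, n_atoms: int) -> StructureModel:
    """Random cloud of Cα atoms across two chains with random pLDDTs, for
    oracle-equivalence tests."""
    atoms = []
    for i in range(n_atoms):
        chain = "A" if i < n_atoms // 2 else "B"
        resnum = i + 1 if chain == "A" else i + 1 - n_atoms // 2
        x, y, z = rng.uniform(-20, 20, 3)
        atoms.append(
            AtomRecord(
                chain_id=chain,
                residue_number=int(resnum),
                residue_name="ALA",
                atom_name="CA",
                element="C",
                x=float(x),
                y=float(y),
                z=float(z),
                plddt=float(rng.uniform(60, 100)),
                is_polymer=True,
            )
        )
    return StructureModel(model_id="random", atoms=atoms, source_format="pdb")
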