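import numpy as np
import pytest

from pairpot.histogram import make_scheme
from pairpot.structure import AtomSite, StructureModel
from pairpot.synthetic import (
    SyntheticSpec,
    generate_decoy_set,
    generate_structure,
    generate_training_set,
)


@pytest.fixture(scope="session")
def training_set():
    """20 clean synthetic structures, lengths 15-30."""
    return generate_training_set(20, (15, 30), seed=11)


@pytest.fixture(scope="session")
def scheme8():
    return make_scheme(8.0)


@pytest.fixture(scope="session")
def helix25():
    return generate_structure(SyntheticSpec(n_residues=25, seed=5))


@pytest.fixture(scope="session")
def decoy_set_small():
    """One decoy set: 25 residues, 9 decoys over the default sigma ladder."""
    return generate_decoy_set(
        SyntheticSpec(n_residues=25, n_decoys=9, seed=21), name="small"
    )


def random_structure(rng: np.random.Generator, n_residues=None):
    """Noisy random-coil structure for oracle-equivalence property tests."""
    n = int(n_residues or rng.integers(4, 12))
    spec = SyntheticSpec(n_residues=n, seed=int(rng.integers(2**31)))
    model = generate_structure(spec)
    jitter = rng.normal(0, 2.0, (model.n_atoms, 3))
    atoms = [
        AtomSite(a.residue_index, a.residue_name, a.atom_name, a.type_id,
                 a.coords + jitter[k])
        for k, a in enumerate(model.atoms)
    ]
    return StructureModel(chain_id="A", atoms=atoms, sequence=model.sequence)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
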