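import numpy as np
import pytest

from piluskit import (
    GeneratorConfig,
    make_synthetic_subunit,
    narrow_config,
    wide_config,
)
from piluskit.model import AssemblyModel, Atom, SubunitModel


@pytest.fixture(scope="session")
def wide_subunit():
    return make_synthetic_subunit(wide_config(seed=11))


@pytest.fixture(scope="session")
def narrow_subunit():
    return make_synthetic_subunit(narrow_config(seed=12))


@pytest.fixture
def identity_frame_assembly():
    """A one-serine subunit whose attachment frame is the identity at the
    origin (N on +x, C on +y), centred on the assembly axis."""
    atoms = [
        Atom(1, "N", "N", "SER", 1, "A", np.array([1.45, 0.0, 0.0])),
        Atom(2, "CA", "C", "SER", 1, "A", np.zeros(3)),
        Atom(3, "C", "C", "SER", 1, "A", np.array([0.0, 1.52, 0.0])),
        Atom(4, "OG", "O", "SER", 1, "A", np.array([1.4, 1.4, 1.4])),
    ]
    subunit = SubunitModel(atoms=atoms, site_residues=[1])
    return AssemblyModel(subunits=[subunit], kind="filament")


def random_cloud_subunit(rng: np.random.Generator, n_atoms: int = 20) -> SubunitModel:
    """A featureless rigid atom cloud for symmetry-operator tests."""
    coords = rng.normal(scale=6.0, size=(n_atoms, 3)) + np.array([9.0, 0.0, 0.0])
    atoms = [
        Atom(i + 1, "CA", "C", "ALA", i + 1, "A", c) for i, c in enumerate(coords)
    ]
    return SubunitModel(atoms=atoms)
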