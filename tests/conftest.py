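import numpy as np
import pytest

from pocketdta import (ResidueCloud, SamplerConfig, sample_surface)
from pocketdta.fixtures import FixtureConfig, make_protein


@pytest.fixture
def single_res_cloud():
    return ResidueCloud(["ALA"], np.zeros((1, 3)), [1.5], ["A"], [1])


@pytest.fixture
def two_res_cloud():
    return ResidueCloud(["ALA", "ALA"], np.array([[0., 0, 0], [4., 0, 0]]),
                        [1.5, 1.5], ["A", "A"], [1, 2])


@pytest.fixture(scope="session")
def toy_protein():
    """50-residue seeded synthetic protein with pocket labels."""
    return make_protein(FixtureConfig(), seed=0)


@pytest.fixture(scope="session")
def toy_surface(toy_protein):
    cloud, _ = toy_protein
    return sample_surface(cloud, SamplerConfig(), seed=0)


@pytest.fixture(scope="session")
def small_protein():
    """40-residue protein for cheaper geometry tests."""
    return make_protein(FixtureConfig(n_residues=40), seed=3)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def pdb_atom_line(serial, name, resname, chain, resi, xyz, occ=1.0,
                  altloc=" ", element=None):
    element = element or name[0]
    return (f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
            f"{resi:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2s}\n")
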