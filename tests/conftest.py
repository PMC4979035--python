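"""Shared fixtures: synthetic systems and fast solver settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polarbind.solvation import PBParams
from polarbind.synthetic_data import Fixture, FixtureSpec, make_fixture

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy() -> Fixture:
    """The default receptor-ligand toy complex (3 designed H-bonds)."""
    return make_fixture(FixtureSpec(kind="toy_complex"))


@pytest.fixture(scope="session")
def helix() -> Fixture:
    """10-residue ideal helix with its i -> i+4 backbone H-bond network."""
    return make_fixture(FixtureSpec(kind="mini_helix", n_residues=10))


@pytest.fixture(scope="session")
def dimer() -> Fixture:
    return make_fixture(FixtureSpec(kind="dimer"))


@pytest.fixture(scope="session")
def born() -> Fixture:
    return make_fixture(FixtureSpec(kind="born_ion"))


@pytest.fixture(scope="session")
def fast_pb() -> PBParams:
    """Coarse PB grid that keeps multi-solve tests fast."""
    return PBParams(grid_density=1.5, grid_padding=6.0, tolerance=1e-7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
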