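import numpy as np
import pytest

from flexgen import (HingeSpec, assign_secondary_structure, make_hinge_pair,
                     make_pockets)
from flexgen.spe import SPEParams

# Fixture-scale SPE schedule: the default 60k iterations/atom is sized for
# real proteins; the hinge peptide converges far earlier.
FAST_SPE = SPEParams(iterations_per_atom=6000)


@pytest.fixture(scope="session")
def hinge_spec():
    return HingeSpec()


@pytest.fixture(scope="session")
def hinge_pair(hinge_spec):
    a, b = make_hinge_pair(hinge_spec)
    return (assign_secondary_structure(a), assign_secondary_structure(b))


@pytest.fixture(scope="session")
def hinge_pockets(hinge_spec, hinge_pair):
    return make_pockets(hinge_pair, hinge_spec, n_decoys=3, seed=0)


@pytest.fixture(scope="session")
def small_pair():
    """A smaller hinge pair for the slow stochastic checks."""
    spec = HingeSpec(n_res_per_arm=5, hinge_angle_a=20.0, hinge_angle_b=70.0)
    a, b = make_hinge_pair(spec)
    return (assign_secondary_structure(a), assign_secondary_structure(b))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
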