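import numpy as np
import pytest

from ebtip.kinetics import KineticParameters
from ebtip.lattice import Lattice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return KineticParameters()


@pytest.fixture
def seed_lattice():
    """Standard 13-protofilament lattice with a 25-dimer GTP seed."""
    return Lattice(n_pf=13, seed_length=25)


@pytest.fixture
def small_lattice():
    """A 3-protofilament, 10-dimer toy lattice for exhaustive checks."""
    return Lattice(n_pf=3, seed_length=10, capacity=64)


def eb1_only_params(**overrides) -> KineticParameters:
    """Parameters with all tubulin/bond/hydrolysis dynamics frozen."""
    zero_tab = {(nuc, b): 0.0 for nuc in ("GTP", "GDP") for b in range(3)}
    base = dict(
        tubulin_conc=0.0,
        k_off_tubulin_base=zero_tab,
        k_hydrolysis=0.0,
        k_lat_form=0.0,
        k_lat_break_base=0.0,
    )
    base.update(overrides)
    return KineticParameters(**base)
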