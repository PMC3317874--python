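import numpy as np
import pytest

from dimerint import energetics, synthetic
from dimerint.structures import AtomRecord


@pytest.fixture
def const_eps_opts():
    return energetics.EnergyOptions(dielectric_mode="constant", dielectric_constant=1.0)


@pytest.fixture
def random_toy_dimer():
    """A jittered, charged toy dimer with both cholesterol proxies."""
    spec = synthetic.DimerFixtureSpec(
        n_residues_per_protomer=8,
        separation=5.5,
        charge_scheme="random",
        jitter=0.3,
        seed=7,
        n_cholesterol=2,
    )
    return synthetic.make_dimer_fixture(spec)


def make_atom(xyz, q=0.0, A=0.0, C=0.0, name="X"):
    return AtomRecord(atom_name=name, element="C", coords=np.asarray(xyz, float),
                      charge_q=q, lj_A=A, lj_C=C)
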