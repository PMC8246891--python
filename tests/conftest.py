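"""Shared fixtures: desk-scale sampled models and micro-networks.

Session scope keeps the expensive pieces (network builds, pilot simulations)
to one instance each; individual tests treat them as read-only.
"""

import numpy as np
import pytest

import bgsim
from bgsim import params as P
from bgsim.network import GLUT, NetworkInstance, SynapseGroup
from bgsim.params import FixedParams, NucleusSpec, Parameterization

FIXTURE_SEED = 11
FIXTURE_SCALE = 0.05


@pytest.fixture(scope="session")
def fixture1():
    """One-channel desk-scale parameterization plus its plausibility table."""
    return bgsim.make_fixture(seed=FIXTURE_SEED, scale=FIXTURE_SCALE,
                              n_channels=1)


@pytest.fixture(scope="session")
def param1(fixture1):
    return fixture1[0]


@pytest.fixture(scope="session")
def table1(fixture1):
    return fixture1[1]


@pytest.fixture(scope="session")
def net1(param1):
    return bgsim.build_network(param1, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def rest1(net1):
    return bgsim.run(net1, duration=2000, warmup=1000, dt=0.1,
                     seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def param3():
    """Three-channel model for selection benches (third channel at baseline)."""
    p = bgsim.sample_parameterization(1, n_channels=3)
    return bgsim.scale_populations(p, 0.05)


def make_micro_net(theta=10.0, v_c=0.0, tau_m=14.0, t_ref=2.0,
                   weight=1.0, kind=GLUT, delay=1.0, n_inputs=1,
                   input_rate=0.0) -> NetworkInstance:
    """A single LIF neuron with one input synapse per generator.

    Gives closed-form-checkable dynamics: constant drive via ``v_c``,
    or precisely timed PSPs via injected input events.
    """
    spec = NucleusSpec(name="GPi", n_per_channel=1, theta=theta, v_c=v_c,
                       tau_m=tau_m, t_ref=t_ref, dendrite_length=1132.0,
                       dendrite_diameter=1.2)
    param = Parameterization(fixed=FixedParams(), nuclei=[spec],
                             projections=[], n_channels=1)
    group = SynapseGroup(
        projection="IN->GPi",
        pre=np.arange(n_inputs, dtype=np.int64),
        post=np.zeros(n_inputs, dtype=np.int64),
        weight=weight, delay=delay, kind=kind, from_inputs=True)
    return NetworkInstance(
        param=param, seed=0,
        nucleus_of=np.full(1, P.NUCLEI.index("GPi"), dtype=np.int8),
        channel_of=np.zeros(1, dtype=np.int16),
        theta=np.array([theta]), tau_m=np.array([tau_m]),
        t_ref=np.array([t_ref]), v_c=np.array([v_c]),
        inp_population=np.full(n_inputs, 2, dtype=np.int8),  # CM/Pf pool code
        inp_channel=np.full(n_inputs, -1, dtype=np.int16),
        inp_rate=np.full(n_inputs, float(input_rate)),
        groups={"IN->GPi": group},
    )
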