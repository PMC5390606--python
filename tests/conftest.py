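import numpy as np
import pytest

import cyclenet as cn


@pytest.fixture(scope="session")
def table1():
    """The packaged 14-gene interaction table."""
    return cn.load_fixture("table1")


@pytest.fixture(scope="session")
def table3():
    """The packaged reference ODE parameter set."""
    return cn.load_fixture("table3")


@pytest.fixture(scope="session")
def network(table1):
    return cn.build_network(table1)


@pytest.fixture(scope="session")
def tmatrix(network):
    return cn.transition_matrix(network)


@pytest.fixture(scope="session")
def reference_samples(table3):
    """RK4 trajectory of the reference system, sampled at h = 0.01 over [0, 5]."""
    traj = cn.simulate_rk4(table3, (1.0, 1.0, 1.0, 1.0, 1.0), h=0.01, t_end=5.0)
    return cn.SampleSet.from_trajectory(traj)


@pytest.fixture(scope="session")
def coarse_samples(reference_samples):
    """Every 25th reference sample (spacing 0.25) for the dynamic-stage tests."""
    return cn.SampleSet(
        times=reference_samples.times[::25],
        states=reference_samples.states[::25],
        labels=reference_samples.labels,
    )


@pytest.fixture
def single_gene_table():
    return cn.InteractionTable(labels=("G1",), codes=((cn.Interaction.NONE,),))
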