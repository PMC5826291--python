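import numpy as np
import pytest

from fgpore.cg_model import ForceField, load_bead_table
from fgpore.sequences import load_builtin


@pytest.fixture(scope="session")
def bead_table():
    return load_bead_table()


@pytest.fixture(scope="session")
def ff():
    return ForceField()


@pytest.fixture(scope="session")
def nsp1():
    return load_builtin("Nsp1")


@pytest.fixture(scope="session")
def nsp1s():
    return load_builtin("Nsp1-S")


@pytest.fixture(scope="session")
def chain_trajectory():
    """A 32-bead bonded chain run shared by thermostat/bond-statistics
    tests; enough degrees of freedom for a tight equipartition estimate."""
    from fgpore.simulator import SimulationConfig, free_system, run_dynamics

    n = 32
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * 0.38 - n * 0.19
    system = free_system(pos, box=(40, 40, 40),
                         bonds=[(i, i + 1) for i in range(n - 1)])
    cfg = SimulationConfig(
        n_steps=40000, n_equilibration=4000, stride=40, seed=11,
        friction=2.0, ramp_fraction=0.0,
    )
    return run_dynamics(system, cfg)
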