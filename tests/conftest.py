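import numpy as np
import pytest

import hexfrac as hf


@pytest.fixture(scope="session")
def table():
    return hf.PotentialTable()


@pytest.fixture()
def small_lattice():
    return hf.build_hexagonal_lattice(10, 10)


@pytest.fixture(scope="session")
def notched_run(table):
    """One shared small notched strain-and-hold trajectory at 300 K."""
    system = hf.insert_notch(hf.build_hexagonal_lattice(40, 40), 20, 4, 2)
    protocol = hf.StrainProtocol(magnitude=0.05, hold_steps=3000)
    config = hf.DynamicsConfig(random_seed=3, series_every=100)
    final, series, switch_log, snapshots = hf.run_constant_strain(
        system, table, protocol, config
    )
    return final, series, switch_log, snapshots


def brute_force_virial(system, table):
    """Independent direct-summation 2-D virial stress oracle (pure loops)."""
    lo = system.positions.min(axis=0)
    hi = system.positions.max(axis=0)
    width = system.box_x if system.box_x is not None else hi[0] - lo[0]
    area = width * (hi[1] - lo[1])
    sigma = np.zeros((2, 2))
    for i, j in system.bonds:
        d = system.positions[i] - system.positions[j]
        if system.box_x is not None:
            d[0] -= system.box_x * round(d[0] / system.box_x)
        r = float(np.hypot(*d))
        pot = hf.resolve_potential(
            table, hf.Species(int(system.species[i])), hf.Species(int(system.species[j]))
        )
        f = hf.pair_force(pot, r) * d / r
        for a in range(2):
            for b in range(2):
                sigma[a, b] += d[a] * f[b]
    for i in range(system.n_blocks):
        if not system.clamped[i]:
            v = system.velocities[i]
            for a in range(2):
                for b in range(2):
                    sigma[a, b] += system.masses[i] * v[a] * v[b]
    return sigma / area
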