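import numpy as np
import pytest

import crndose as cd


@pytest.fixture(scope="session")
def toy():
    return cd.build_mapk_toy()


@pytest.fixture(scope="session")
def toy_basis(toy):
    return cd.find_conservation_laws(toy)


@pytest.fixture(scope="session")
def toy_phys(toy, toy_basis):
    res = cd.solve_equilibrium(toy, toy_basis, toy.x0, seed=1)
    assert res.converged
    return res.x_e


@pytest.fixture(scope="session")
def toy_gof(toy):
    """Complete K-Ras gain of function: network and its equilibrium."""
    mut = cd.apply_gof(toy, cd.MutationSpec("KRAS", "GoF", 0.0))
    basis = cd.find_conservation_laws(mut)
    res = cd.solve_equilibrium(mut, basis, toy.x0, seed=1)
    assert res.converged
    return mut, res.x_e


@pytest.fixture()
def enzyme_cycle():
    """E + S <-> ES -> E + P plus P -> S recovery; two moieties (E, S)."""
    return cd.Network(
        [
            cd.Species("E", 10.0, ("E",)),
            cd.Species("S", 50.0, ("S",)),
            cd.Species("ES", 0.0, ("E", "S")),
            cd.Species("P", 0.0, ("S",)),
        ],
        [
            cd.Reaction("bind", (("E", 1), ("S", 1)), (("ES", 1),), 1e-2),
            cd.Reaction("unbind", (("ES", 1),), (("E", 1), ("S", 1)), 0.1),
            cd.Reaction("cat", (("ES", 1),), (("E", 1), ("P", 1)), 0.5),
            cd.Reaction("recover", (("P", 1),), (("S", 1),), 0.05),
        ],
    )


def relerr(a, b, floor=1e-9):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), floor))
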