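"""Fluxes, Jacobian, trajectory integration and its oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

import crndose as cd
from crndose.network import loads_network
from conftest import relerr


def test_bimolecular_flux():
    net = loads_network(
        "SPECIES A 3.0\nSPECIES B 4.0\nSPECIES C 0.0\nREACTION r A + B -> C ; k=2\n"
    )
    v = cd.reaction_fluxes(net, np.array([3.0, 4.0, 0.0]))
    assert v.tolist() == [24.0]


def test_second_order_flux_and_zero_reactant():
    net = loads_network("SPECIES A 3.0\nSPECIES B 0.0\nREACTION r 2 A -> B ; k=1\n")
    assert cd.reaction_fluxes(net, np.array([3.0, 0.0])).tolist() == [9.0]
    assert cd.reaction_fluxes(net, np.array([0.0, 1.0])).tolist() == [0.0]


def test_rhs_detailed_balance_is_zero():
    net = cd.build_reversible_pair(2.0, 1.0, 3.0)
    assert np.allclose(cd.ode_rhs(net, np.array([1.0, 2.0])), 0.0)
    assert cd.ode_rhs(net, np.array([5.0, 0.0])).tolist() == [-10.0, 10.0]


def test_rhs_rejects_negative_state():
    net = cd.build_reversible_pair(1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        cd.ode_rhs(net, np.array([-1.0, 2.0]))


def test_conservation_of_rhs_exact(toy, toy_basis):
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.uniform(0, 50, toy.n)
        assert np.abs(toy_basis.N @ cd.ode_rhs(toy, x)).max() < 1e-10


def test_jacobian_simple():
    net = loads_network("SPECIES A 1.0\nSPECIES B 0.0\nREACTION r A -> B ; k=1\n")
    J = cd.jacobian(net, np.array([1.0, 0.0]))
    assert J.tolist() == [[-1.0, 0.0], [1.0, 0.0]]


def _fd_jacobian(net, x, h=1e-6):
    n = net.n
    J = np.zeros((n, n))
    for i in range(n):
        step = h * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += step
        xm = x.copy(); xm[i] = max(xm[i] - step, 0.0)
        J[:, i] = (cd.ode_rhs(net, xp) - cd.ode_rhs(net, xm)) / (xp[i] - xm[i])
    return J


@pytest.mark.parametrize("seed", range(5))
def test_jacobian_matches_finite_differences(seed):
    net = cd.random_mass_action_network(5, 8, seed)
    rng = np.random.default_rng(seed + 100)
    x = rng.uniform(0.5, 20.0, net.n)
    J = cd.jacobian(net, x)
    Jfd = _fd_jacobian(net, x)
    scale = np.abs(J).max() + 1.0
    assert np.abs(J - Jfd).max() / scale < 1e-5


def test_jacobian_at_zero_concentration(enzyme_cycle):
    x = np.array([10.0, 0.0, 0.0, 0.0])
    J = cd.jacobian(enzyme_cycle, x)
    # d(bind flux)/dS = k * E at S = 0
    assert J[enzyme_cycle.index("ES"), enzyme_cycle.index("S")] == pytest.approx(0.01 * 10.0)


def test_exponential_decay_closed_form():
    k = np.log(2.0)
    net = loads_network(f"SPECIES A 8.0\nSPECIES B 0.0\nREACTION r A -> B ; k={k}\n")
    traj = cd.simulate(net, net.x0, np.linspace(0, 3.0, 7))
    expected = 8.0 * np.exp(-k * traj.times)
    assert relerr(traj["A"][1:], expected[1:]) < 1e-6


def test_first_order_network_matches_matrix_exponential():
    net = loads_network(
        "SPECIES A 5.0\nSPECIES B 1.0\nSPECIES C 0.0\n"
        "REACTION f1 A -> B ; k=0.7\nREACTION r1 B -> A ; k=0.3\n"
        "REACTION f2 B -> C ; k=0.5\nREACTION r2 C -> B ; k=0.2\n"
    )
    # rate matrix: xdot = M x for unimolecular networks
    M = np.zeros((3, 3))
    for j, rx in enumerate(net.reactions):
        i = net.index(rx.reactants[0][0])
        M[:, i] += net.S[:, j] * rx.k
    times = np.linspace(0, 10, 6)
    traj = cd.simulate(net, net.x0, times, rtol=1e-10, atol=1e-14)
    for t, row in zip(times[1:], traj.states[1:]):
        assert relerr(row, expm(M * t) @ net.x0) < 1e-8


def _rk4(net, x0, t_end, steps):
    """Fixed-step RK4 in extended precision: an integration oracle."""
    x = np.array(x0, dtype=np.longdouble)
    h = np.longdouble(t_end) / steps
    S = net.S.astype(np.longdouble)
    A = net.reactant_matrix
    k = net.k.astype(np.longdouble)

    def rhs(y):
        return S @ (k * np.prod(np.maximum(y, 0)[:, None] ** A, axis=0))

    for _ in range(steps):
        k1 = rhs(x)
        k2 = rhs(x + h / 2 * k1)
        k3 = rhs(x + h / 2 * k2)
        k4 = rhs(x + h * k3)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return np.array(x, dtype=float)


def test_nonlinear_trajectory_matches_rk4_oracle(enzyme_cycle):
    t_end = 20.0
    traj = cd.simulate(enzyme_cycle, enzyme_cycle.x0, np.array([0.0, t_end]))
    oracle = _rk4(enzyme_cycle, enzyme_cycle.x0, t_end, 40000)
    assert relerr(traj.final, oracle, floor=1e-6) < 1e-6


def test_trajectory_conserves_moieties(toy, toy_basis):
    traj = cd.simulate(toy, toy.x0, np.geomspace(1e-2, 1e5, 40))
    totals0 = toy_basis.N @ traj.states[0]
    drift = np.abs(toy_basis.N @ traj.states.T - totals0[:, None]).max()
    assert drift <= 1e-6 * np.abs(totals0).max()
    assert traj.states.min() >= 0.0


def test_event_at_zero_equals_incremented_x0():
    net = cd.build_reversible_pair(1.0, 1.0, 4.0)
    grid = np.linspace(0, 5, 11)
    ev = cd.AdministrationEvent(0.0, "A", 2.0)
    t1 = cd.simulate(net, net.x0, grid, events=[ev])
    x0b = net.x0.copy()
    x0b[0] += 2.0
    t2 = cd.simulate(net, x0b, grid)
    assert np.allclose(t1.states, t2.states, rtol=1e-8, atol=1e-10)


def test_mid_run_event_adds_mass():
    net = cd.build_reversible_pair(1.0, 1.0, 4.0)
    grid = np.linspace(0, 40, 81)
    ev = cd.AdministrationEvent(10.0, "A", 6.0)
    traj = cd.simulate(net, net.x0, grid, events=[ev])
    total = traj["A"] + traj["B"]
    assert np.allclose(total[grid <= 10.0], 4.0, atol=1e-8)
    assert np.allclose(total[grid > 10.5], 10.0, atol=1e-8)
    # relaxes to the new equilibrium 5/5
    assert abs(traj["A"][-1] - 5.0) < 1e-6


def test_simulate_to_equilibrium_reversible_pair():
    net = cd.build_reversible_pair(2.0, 1.0, 3.0)
    res = cd.simulate_to_equilibrium(net, net.x0)
    assert res.converged and res.method == "ode"
    assert np.allclose(res.x_e, [1.0, 2.0], atol=1e-8)


def test_trajectory_csv_export(tmp_path, toy):
    traj = cd.simulate(toy, toy.x0, np.linspace(0, 10, 5))
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    text = path.read_text()
    assert text.splitlines()[0].startswith("time_s,")
    assert len(text.splitlines()) == 6
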