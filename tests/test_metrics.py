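"""Effect profiles, the modified geometric mean, dose scans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crndose as cd
from crndose.metrics import G_OFFSET


def test_delta_profile_basic():
    prof = cd.delta_profile(np.array([2.0, 0.0, 3.0]), np.array([1.0, 4.0, 3.0]))
    assert prof.values.tolist() == [1.0, -1.0, 0.0]


def test_delta_profile_identity():
    x = np.array([1.0, 2.0, 3.0])
    assert cd.delta_profile(x, x).values.tolist() == [0.0, 0.0, 0.0]


def test_delta_profile_zero_reference_rejected():
    with pytest.raises(cd.NetworkError) as exc:
        cd.delta_profile(np.ones(2), np.array([1.0, 0.0]))
    assert exc.value.code == "ZERO_REFERENCE"


@given(
    st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=8, max_size=8),
    st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=8, max_size=8),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_delta_sign_matches_raw_difference(comp, phys):
    comp = np.array(comp)
    phys = np.array(phys)
    prof = cd.delta_profile(comp, phys)
    assert np.all(np.sign(prof.values) == np.sign(comp - phys))
    assert np.all(prof.values >= -1.0)


def test_top_variations_ordering():
    phys = np.array([1.0, 1.0, 1.0])
    comp = np.array([6.0, 2.0, 4.0])
    table = cd.top_variations(comp, phys, ("a", "b", "c"), m=3)
    assert list(table["species"]) == ["a", "c", "b"]
    assert list(table["abs_change_nM"]) == [5.0, 3.0, 1.0]


def test_top_variations_stable_under_ties():
    x = np.array([1.0, 2.0, 3.0])
    table = cd.top_variations(x, x, ("a", "b", "c"))
    assert list(table["species"]) == ["a", "b", "c"]
    assert np.all(table["abs_change_nM"] == 0.0)


def test_geometric_index_identities():
    assert cd.geometric_index(np.zeros(7)) == pytest.approx(0.0, abs=1e-15)
    assert cd.geometric_index(np.ones(5)) == pytest.approx(1.0, rel=1e-12)
    # independent arithmetic oracle for n=2, d=(0,1)
    oracle = math.sqrt(G_OFFSET * (1.0 + G_OFFSET)) - G_OFFSET
    assert cd.geometric_index(np.array([0.0, 1.0])) == pytest.approx(oracle, rel=1e-12)
    assert oracle == pytest.approx(9.99001e-4, rel=1e-4)


def test_geometric_index_empty_rejected():
    with pytest.raises(ValueError):
        cd.geometric_index(np.array([]))


@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=12))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_geometric_index_properties(d):
    d = np.array(d)
    g = cd.geometric_index(d)
    assert g >= -1e-12
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(d))
    assert cd.geometric_index(d[perm]) == pytest.approx(g, rel=1e-9, abs=1e-12)
    assert cd.geometric_index(np.abs(d)) == pytest.approx(g, rel=1e-9, abs=1e-12)


def test_delta_norm_decreases_with_milder_gof(toy, toy_basis, toy_phys):
    norms = []
    for lam in (0.0, 0.3, 0.6, 1.0):
        mut = cd.apply_gof(toy, cd.MutationSpec("KRAS", "GoF", lam))
        res = cd.solve_equilibrium(mut, cd.find_conservation_laws(mut), toy.x0, seed=1)
        x = np.array([res.x_e[mut.index(n)] for n in toy.species_names])
        norms.append(np.abs(cd.delta_profile(x, toy_phys, toy.species_names).values).max())
    assert norms == sorted(norms, reverse=True)
    assert norms[-1] == 0.0


@pytest.fixture(scope="module")
def scan_setup(toy, toy_basis, toy_phys, toy_gof):
    mut, x_mut = toy_gof
    rafi = cd.DrugSpec("RAFi", "competitive", ("pRaf",))
    meki = cd.DrugSpec("MEKi", "allosteric", ("MEK", "pMEK", "ppMEK"))
    return mut, x_mut, toy_phys, rafi, meki


def test_dose_scan_zero_dose_is_mutation_baseline(scan_setup, toy):
    mut, x_mut, phys, rafi, _ = scan_setup
    scan = cd.dose_scan_1d(mut, x_mut, phys, rafi, np.array([0.0, 80.0]), seed=2)
    baseline = cd.geometric_index(cd.delta_profile(x_mut, phys, toy.species_names))
    assert scan.G_values[0] == pytest.approx(baseline, rel=1e-12)
    assert scan.failures == []


def test_dose_scan_interior_minimum(scan_setup):
    mut, x_mut, phys, rafi, _ = scan_setup
    grid = np.linspace(0.0, 400.0, 11)
    scan = cd.dose_scan_1d(mut, x_mut, phys, rafi, grid, seed=2)
    i = list(grid).index(scan.argmin[0])
    assert 0 < i < len(grid) - 1
    assert scan.G_min < scan.G_values[0]
    assert scan.G_min < scan.G_values[-1]


def test_dose_scan_argmin_matches_exhaustive(scan_setup):
    mut, x_mut, phys, rafi, _ = scan_setup
    grid = np.linspace(0.0, 200.0, 6)
    scan = cd.dose_scan_1d(mut, x_mut, phys, rafi, grid, seed=2)
    assert scan.argmin[0] == grid[int(np.nanargmin(scan.G_values))]


def test_dose_scan_2d_marginals_exact(scan_setup):
    mut, x_mut, phys, rafi, meki = scan_setup
    gA = np.array([0.0, 60.0, 120.0])
    gB = np.array([0.0, 100.0])
    s2 = cd.dose_scan_2d(mut, x_mut, phys, rafi, meki, gA, gB, seed=2)
    s1A = cd.dose_scan_1d(mut, x_mut, phys, rafi, gA, seed=2)
    s1B = cd.dose_scan_1d(mut, x_mut, phys, meki, gB, seed=2)
    assert np.array_equal(s2.G_values[:, 0], s1A.G_values)
    assert np.array_equal(s2.G_values[0, :], s1B.G_values)
    flat = np.unravel_index(np.nanargmin(s2.G_values), s2.G_values.shape)
    assert s2.argmin == (gA[flat[0]], gB[flat[1]])


def test_activated_fraction_bounds_and_total(toy, toy_basis):
    traj = cd.simulate(toy, toy.x0, np.geomspace(1, 1e5, 30))
    frac = cd.activated_fraction(traj, "ppERK", toy_basis, "ERK")
    assert np.all(frac >= 0.0) and np.all(frac <= 1.0 + 1e-9)
    # all mass on the active species gives fraction 1
    x_all = np.zeros(toy.n)
    x_all[toy.index("ppERK")] = 120.0
    x_all[toy.index("RasGDP")] = 1.0
    traj2 = cd.Trajectory(np.array([0.0, 1.0]), np.vstack([x_all, x_all]), toy.species_names)
    frac2 = cd.activated_fraction(traj2, "ppERK", toy_basis, "ERK")
    assert frac2.tolist() == [1.0, 1.0]


def test_activated_fraction_zero_total_rejected(toy, toy_basis):
    x = np.zeros(toy.n)
    traj = cd.Trajectory(np.array([0.0, 1.0]), np.vstack([x, x]), toy.species_names)
    with pytest.raises(cd.NetworkError):
        cd.activated_fraction(traj, "ppERK", toy_basis, "ERK")
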