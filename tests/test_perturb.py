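"""Mutation operators and drug augmentation."""

import numpy as np
import pytest

import crndose as cd
from conftest import relerr


GOF0 = cd.MutationSpec("KRAS", "GoF", 0.0)


def test_gof_identity_at_level_one(toy):
    assert cd.apply_gof(toy, cd.MutationSpec("KRAS", "GoF", 1.0)) is toy


def test_gof_scales_tagged_rates(toy):
    mut = cd.apply_gof(toy, cd.MutationSpec("KRAS", "GoF", 0.3))
    for rx, rx0 in zip(mut.reactions, toy.reactions):
        if "deactivation:KRAS" in rx0.tags:
            assert rx.k == pytest.approx(0.3 * rx0.k)
        else:
            assert rx.k == rx0.k


def test_gof_complete_removes_reactions(toy):
    mut = cd.apply_gof(toy, GOF0)
    assert mut.r == toy.r - 3
    assert not any("deactivation:KRAS" in rx.tags for rx in mut.reactions)


def test_gof_requires_tags(enzyme_cycle):
    with pytest.raises(cd.NetworkError) as exc:
        cd.apply_gof(enzyme_cycle, cd.MutationSpec("KRAS", "GoF", 0.0))
    assert exc.value.code == "MISSING_DEACTIVATION_TAGS"


def test_gof_raises_active_form(toy, toy_basis, toy_phys):
    mut = cd.apply_gof(toy, GOF0)
    res = cd.solve_equilibrium(mut, cd.find_conservation_laws(mut), toy.x0, seed=1)
    assert res.converged
    assert res.x_e[mut.index("RasGTP")] > toy_phys[toy.index("RasGTP")]


def test_gof_monotone_in_level(toy, toy_basis):
    prev = np.inf
    for lam in (0.0, 0.3, 0.6, 1.0):
        mut = cd.apply_gof(toy, cd.MutationSpec("KRAS", "GoF", lam))
        res = cd.solve_equilibrium(mut, cd.find_conservation_laws(mut), toy.x0, seed=1)
        active = res.x_e[mut.index("RasGTP")]
        assert active <= prev + 1e-8
        prev = active


def test_lof_zeroes_protein_and_compounds(toy):
    x = cd.apply_lof(toy, toy.x0, cd.MutationSpec("PTEN", "LoF"))
    for i, sp in enumerate(toy.species):
        if sp.contains("PTEN"):
            assert x[i] == 0.0
        else:
            assert x[i] == toy.x0[i]


def test_lof_delta_minus_one_on_zeroed_moieties(toy, toy_basis, toy_phys):
    x0 = cd.apply_lof(toy, toy.x0, cd.MutationSpec("PTEN", "LoF"))
    res = cd.solve_equilibrium(toy, toy_basis, x0, seed=1)
    prof = cd.delta_profile(res.x_e, toy_phys, toy.species_names)
    assert prof["PTEN"] == -1.0
    assert prof["PTEN_Sub"] == -1.0


def test_lof_unknown_protein(toy):
    with pytest.raises(cd.NetworkError) as exc:
        cd.apply_lof(toy, toy.x0, cd.MutationSpec("NOSUCH", "LoF"))
    assert exc.value.code == "UNKNOWN_PROTEIN"


def test_compose_mutations_order_independent(toy):
    specs = [GOF0, cd.MutationSpec("PTEN", "LoF")]
    net1, x1 = cd.compose_mutations(toy, toy.x0, specs)
    net2, x2 = cd.compose_mutations(toy, toy.x0, specs[::-1])
    assert net1 == net2
    assert np.array_equal(x1, x2)
    r1 = cd.solve_equilibrium(net1, cd.find_conservation_laws(net1), x1, seed=1)
    r2 = cd.solve_equilibrium(net2, cd.find_conservation_laws(net2), x2, seed=2)
    assert relerr(r1.x_e, r2.x_e, floor=1e-6) < 1e-6


def test_compose_empty_is_identity(toy):
    net, x = cd.compose_mutations(toy, toy.x0, [])
    assert net is toy
    assert np.array_equal(x, toy.x0)


def test_compose_conflicting_specs(toy):
    with pytest.raises(cd.NetworkError) as exc:
        cd.compose_mutations(
            toy, toy.x0, [GOF0, cd.MutationSpec("KRAS", "GoF", 0.5)]
        )
    assert exc.value.code == "CONFLICTING_MUTATIONS"


# --- drugs ---------------------------------------------------------------


def test_add_drug_counts(toy):
    spec = cd.DrugSpec("RAFi", "competitive", ("pRaf",), c0=50.0, degradation_rate=1e-5)
    aug = cd.add_drug(toy, spec)
    assert aug.n == toy.n + 2  # drug + one complex
    assert aug.r == toy.r + 3  # on, off, degradation
    assert aug.species[aug.index("RAFi")].x0 == 50.0
    comp = aug.species[aug.index("RAFi_pRaf")].composition
    assert set(comp) == {"RAFi", "Raf"}


def test_add_drug_allosteric_multi_target(toy):
    spec = cd.DrugSpec("MEKi", "allosteric", ("MEK", "pMEK", "ppMEK"), c0=10.0)
    aug = cd.add_drug(toy, spec)
    assert aug.n == toy.n + 4
    assert aug.r == toy.r + 6
    # bound forms appear only in their own binding reactions: sequestration
    for t in spec.targets:
        cname = spec.complex_name(t)
        touching = [rx for rx in aug.reactions if any(
            n == cname for n, _ in rx.reactants + rx.products)]
        assert {rx.id for rx in touching} == {f"MEKi_on_{t}", f"MEKi_off_{t}"}


def test_add_drug_name_collision(toy):
    with pytest.raises(cd.NetworkError):
        cd.add_drug(toy, cd.DrugSpec("RasGTP", "competitive", ("pRaf",)))


def test_drug_moiety_conserved_without_degradation(toy, toy_gof):
    mut, x_mut = toy_gof
    spec = cd.DrugSpec("RAFi", "competitive", ("pRaf",), c0=30.0)
    aug = cd.add_drug(mut, spec)
    basis = cd.find_conservation_laws(aug)
    row = basis.row_for_elemental("RAFi")
    x_init = cd.perturb.extend_state(aug, mut, x_mut, spec)
    traj = cd.simulate(aug, x_init, np.geomspace(1, 1e5, 30))
    total = traj["RAFi"] + traj["RAFi_pRaf"]
    assert np.abs(total - 30.0).max() < 1e-6 * 30.0
    assert basis.N[row] @ x_init == pytest.approx(30.0)


def test_drug_total_decays_with_degradation(toy, toy_gof):
    mut, x_mut = toy_gof
    spec = cd.DrugSpec(
        "RAFi", "competitive", ("pRaf",), c0=30.0,
        degradation_rate=cd.DBF_DEGRADATION_RATE,
    )
    aug = cd.add_drug(mut, spec)
    x_init = cd.perturb.extend_state(aug, mut, x_mut, spec)
    traj = cd.simulate(aug, x_init, np.geomspace(10, 5e7, 30))
    total = traj["RAFi"] + traj["RAFi_pRaf"]
    assert total[0] == pytest.approx(30.0, rel=1e-6)
    # binding shelters the drug, so decay is slower than exp(-kt) but strict
    assert np.all(np.diff(total) < 0)
    assert total[-1] < 0.1 * total[0]


def test_zero_dose_equilibrium_unchanged(toy, toy_gof):
    mut, x_mut = toy_gof
    spec = cd.DrugSpec("RAFi", "competitive", ("pRaf",), c0=0.0)
    res, aug = cd.drug_loaded_equilibrium(mut, x_mut, spec, seed=1)
    assert res.converged
    x_orig = np.array([res.x_e[aug.index(n)] for n in mut.species_names])
    assert relerr(x_orig, x_mut, floor=1e-9) < 1e-6


def test_saturating_dose_shuts_down_cascade(toy, toy_gof):
    mut, x_mut = toy_gof
    spec = cd.DrugSpec("RAFi", "competitive", ("pRaf",), c0=5000.0)
    res, aug = cd.drug_loaded_equilibrium(mut, x_mut, spec, seed=1)
    assert res.converged
    assert res.x_e[aug.index("ppERK")] < 0.01 * x_mut[mut.index("ppERK")]


def test_final_equilibrium_independent_of_schedule(toy, toy_gof):
    """A 12-minute delay in the bolus changes the transient, not the
    asymptotic state."""
    mut, x_mut = toy_gof
    spec = cd.DrugSpec("RAFi", "competitive", ("pRaf",), c0=80.0)
    aug = cd.add_drug(mut, spec)
    x_now = cd.perturb.extend_state(aug, mut, x_mut, spec)
    r_now = cd.simulate_to_equilibrium(aug, x_now)
    x_later = x_now.copy()
    x_later[aug.index("RAFi")] = 0.0
    traj = cd.simulate(
        aug, x_later, np.linspace(0, 3000, 20),
        events=[cd.AdministrationEvent(720.0, "RAFi", 80.0)],
    )
    r_later = cd.simulate_to_equilibrium(aug, traj.final)
    assert relerr(r_now.x_e, r_later.x_e, floor=1e-6) < 1e-6
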