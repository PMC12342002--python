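"""In-silico mutations and drug loading.

Loss of function (LoF) projects the initial state: the mutated protein and
every compound containing it are zeroed, which shrinks the corresponding
moiety totals, and all later equilibria live on the reduced compatibility
class.  Gain of function (GoF) edits the network: every reaction tagged
``deactivation:<GENE>`` has its rate scaled by the retained fraction
``lambda`` in [0, 1]; at ``lambda = 0`` the reactions are removed outright.
Mutations commute, so a set of them can be applied in any order.

Drugs are modelled structurally: the free drug and one bound complex per
target are appended as new species, with mass-action binding/unbinding
reactions.  A *competitive* inhibitor binds the catalytically active target
form, sequestering the enzyme; an *allosteric* inhibitor binds all listed
phosphoforms of the target.  Bound complexes take part in no other
reaction, so inhibition emerges from sequestration alone — no modified rate
laws.  Optional first-order degradation (``drug -> 0``) and a scheduled
administration time support time-course studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .conservation import find_conservation_laws
from .dynamics import simulate_to_equilibrium
from .equilibrium import EquilibriumResult, solve_equilibrium
from .network import Network, NetworkError, Reaction, Species

__all__ = [
    "MutationSpec",
    "DrugSpec",
    "apply_gof",
    "apply_lof",
    "compose_mutations",
    "add_drug",
    "drug_loaded_equilibrium",
    "DBF_DEGRADATION_RATE",
]

# Dabrafenib first-order degradation constant, s^-1
DBF_DEGRADATION_RATE = 5.79e-6

# fixture binding kinetics (no published constants to adopt)
DEFAULT_K_ON = 1e-3  # nM^-1 s^-1
DEFAULT_K_OFF = 1e-2  # s^-1


@dataclass(frozen=True)
class MutationSpec:
    """A single-gene mutation.

    ``level`` is the GoF fraction of the physiological de-activation rates
    that is retained: 0 = complete mutation, 1 = no mutation.  LoF is always
    complete.
    """

    protein: str
    kind: str  # "LoF" | "GoF"
    level: float = 0.0

    def __post_init__(self):
        if self.kind not in ("LoF", "GoF"):
            raise ValueError(f"kind must be LoF or GoF, got {self.kind!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"level must lie in [0, 1], got {self.level}")


@dataclass(frozen=True)
class DrugSpec:
    """A targeted inhibitor added to the network.

    ``c0`` is the initial (= total) drug concentration; ``schedule_time``
    delays the bolus for time-course studies (the final equilibrium does not
    depend on it).
    """

    name: str
    mechanism: str  # "competitive" | "allosteric"
    targets: tuple[str, ...]
    k_on: float = DEFAULT_K_ON
    k_off: float = DEFAULT_K_OFF
    c0: float = 0.0
    degradation_rate: float = 0.0
    schedule_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.mechanism not in ("competitive", "allosteric"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("k_on and k_off must be > 0")
        if self.c0 < 0 or self.degradation_rate < 0 or self.schedule_time < 0:
            raise ValueError("c0, degradation_rate, schedule_time must be >= 0")
        if not self.targets:
            raise ValueError("drug needs at least one target")

    def complex_name(self, target: str) -> str:
        return f"{self.name}_{target}"


# ---------------------------------------------------------------------------
# mutations


def _deactivation_tag(protein: str) -> str:
    return f"deactivation:{protein}"


def apply_gof(net: Network, spec: MutationSpec) -> Network:
    """Scale (or remove, at level 0) the de-activation reactions of a gene."""
    if spec.kind != "GoF":
        raise ValueError("apply_gof requires a GoF spec")
    tag = _deactivation_tag(spec.protein)
    tagged = [rx for rx in net.reactions if tag in rx.tags]
    if not tagged:
        raise NetworkError(
            "MISSING_DEACTIVATION_TAGS",
            f"no reaction tagged {tag!r}; cannot model GoF of {spec.protein}",
        )
    if spec.level == 1.0:
        return net
    if spec.level == 0.0:
        reactions = [rx for rx in net.reactions if tag not in rx.tags]
    else:
        reactions = [
            replace(rx, k=rx.k * spec.level) if tag in rx.tags else rx
            for rx in net.reactions
        ]
    return net.with_reactions(reactions)


def apply_lof(net: Network, x0: np.ndarray, spec: MutationSpec) -> np.ndarray:
    """Zero the protein and every compound containing it in the initial state."""
    if spec.kind != "LoF":
        raise ValueError("apply_lof requires a LoF spec")
    x0 = np.asarray(x0, dtype=float).copy()
    hit = [i for i, sp in enumerate(net.species) if sp.contains(spec.protein)]
    if not hit:
        raise NetworkError(
            "UNKNOWN_PROTEIN", f"{spec.protein} occurs in no species composition"
        )
    x0[hit] = 0.0
    return x0


def compose_mutations(
    net: Network, x0: np.ndarray, specs: Sequence[MutationSpec]
) -> tuple[Network, np.ndarray]:
    """Apply several mutations at once; the result is order-independent
    because GoF edits rates and LoF edits the initial state."""
    seen: dict[str, MutationSpec] = {}
    for spec in specs:
        if spec.protein in seen and seen[spec.protein] != spec:
            raise NetworkError(
                "CONFLICTING_MUTATIONS", f"duplicate specs for {spec.protein}"
            )
        seen[spec.protein] = spec
    x = np.asarray(x0, dtype=float).copy()
    out = net
    for spec in sorted(seen.values(), key=lambda s: (s.kind, s.protein)):
        if spec.kind == "GoF":
            out = apply_gof(out, spec)
        else:
            x = apply_lof(out, x, spec)
    return out, x


# ---------------------------------------------------------------------------
# drugs


def add_drug(net: Network, spec: DrugSpec) -> Network:
    """Augment the network with the drug, its target complexes and the
    binding/unbinding (and optional degradation) reactions."""
    if spec.name in net:
        raise NetworkError("NAME_COLLISION", f"species {spec.name} already exists")
    for t in spec.targets:
        if t not in net:
            raise NetworkError("UNKNOWN_SPECIES", f"drug target {t}")
        if spec.complex_name(t) in net:
            raise NetworkError("NAME_COLLISION", spec.complex_name(t))

    species = list(net.species)
    x0_drug = spec.c0 if spec.schedule_time == 0 else 0.0
    species.append(Species(spec.name, x0_drug, composition=(spec.name,)))
    for t in spec.targets:
        t_sp = net.species[net.index(t)]
        t_comp = t_sp.composition if t_sp.composition is not None else (t,)
        species.append(
            Species(spec.complex_name(t), 0.0, composition=(spec.name, *t_comp))
        )

    drug_tag = frozenset({f"drug:{spec.name}"})
    reactions = list(net.reactions)
    for t in spec.targets:
        c = spec.complex_name(t)
        reactions.append(
            Reaction(f"{spec.name}_on_{t}", ((spec.name, 1), (t, 1)), ((c, 1),), spec.k_on, drug_tag)
        )
        reactions.append(
            Reaction(f"{spec.name}_off_{t}", ((c, 1),), ((spec.name, 1), (t, 1)), spec.k_off, drug_tag)
        )
    if spec.degradation_rate > 0:
        reactions.append(
            Reaction(
                f"{spec.name}_degradation",
                ((spec.name, 1),),
                (),
                spec.degradation_rate,
                drug_tag | {"degradation"},
            )
        )
    return Network(species, reactions, net.declared_conservations)


def extend_state(net_aug: Network, net: Network, x: np.ndarray, spec: DrugSpec) -> np.ndarray:
    """Lift a state of ``net`` into ``net_aug``: free drug at c0, complexes 0."""
    x_aug = np.zeros(net_aug.n)
    for i, sp in enumerate(net.species):
        x_aug[net_aug.index(sp.name)] = x[i]
    x_aug[net_aug.index(spec.name)] = spec.c0
    return x_aug


def drug_loaded_equilibrium(
    net_mut: Network,
    x_tilde_e: np.ndarray,
    spec: DrugSpec,
    seed: int = 0,
    method: str = "nlpc",
    **solver_kwargs,
) -> tuple[EquilibriumResult, Network]:
    """Equilibrium of the drug-augmented network started from the mutated
    equilibrium plus the drug bolus.

    Returns the :class:`EquilibriumResult` (state in augmented coordinates)
    and the augmented network.  With a positive degradation rate the drug
    moiety is no longer conserved and the drug washes out at equilibrium;
    dose scans therefore use degradation-free specs.
    """
    net_aug = add_drug(net_mut, spec)
    x_init = extend_state(net_aug, net_mut, np.asarray(x_tilde_e, dtype=float), spec)
    if method == "ode":
        res = simulate_to_equilibrium(net_aug, x_init, **solver_kwargs)
    else:
        basis = find_conservation_laws(net_aug)
        res = solve_equilibrium(net_aug, basis, x_init, seed=seed, **solver_kwargs)
    return res, net_aug
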