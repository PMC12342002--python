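"""Synthetic fixture networks.

The central fixture is a desk-scale mass-action cascade with the structure
of the K-Ras/B-Raf/MEK/ERK module: a GTPase cycle (GEF-catalysed loading,
GAP-catalysed hydrolysis tagged as K-Ras de-activation), tiered enzymatic
phosphorylation with explicit enzyme-substrate complexes (no
Michaelis-Menten reduction, so every moiety conservation law is exact),
per-tier phosphatases, and a decoupled PTEN-analog branch for
loss-of-function experiments.  Every species carries composition metadata,
the conservation basis is weakly elemented (one law per protein moiety),
and the physiological equilibrium is strictly positive.

Rates follow typical signalling scales: association ~1e-3 /nM/s,
dissociation ~0.1 /s, catalysis ~0.1-1 /s, totals 10-120 nM.  GAP and
phosphatase activity dominate at rest, so active forms sit low
physiologically and rise sharply under a K-Ras gain of function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import Network, NetworkError, Reaction, Species, load_network

__all__ = [
    "CascadeParams",
    "build_mapk_toy",
    "build_reversible_pair",
    "random_mass_action_network",
    "load_crcrn",
]


_DEFAULT_TOTALS = {
    "Ras": 100.0,
    "GEF": 10.0,
    "GAP": 20.0,
    "Raf": 100.0,
    "MEK": 120.0,
    "ERK": 120.0,
    "Pase1": 50.0,
    "Pase2": 30.0,
    "Pase3": 60.0,
    "PTEN": 50.0,
    "Sub": 80.0,
}

_DEFAULT_RATES = {
    "bind": 1e-3,  # nM^-1 s^-1
    "unbind": 0.1,  # s^-1
    "gef_cat": 0.1,
    "gap_cat": 5.0,
    "kinase_cat": 0.5,
    "phosphatase_cat": 0.5,
    "pten_cat": 0.2,
    "sub_recovery": 0.05,
}


@dataclass(frozen=True)
class CascadeParams:
    """Shape and scale of the toy cascade.

    ``double_phospho[t]`` switches tier ``t`` to a two-step
    phosphorylation cycle (default: tiers 2 and 3, the MEK/ERK analogs).
    ``rate_scales`` multiplies the per-class default rates.
    """

    n_tiers: int = 3
    double_phospho: tuple[bool, ...] = (False, True, True)
    totals: dict = field(default_factory=dict)
    rate_scales: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_tiers < 1:
            raise ValueError("n_tiers must be >= 1")
        dp = tuple(self.double_phospho)[: self.n_tiers]
        dp = dp + (True,) * (self.n_tiers - len(dp))
        object.__setattr__(self, "double_phospho", dp)
        for v in self.totals.values():
            if v <= 0:
                raise ValueError("totals must be > 0")


def _tier_names(n_tiers: int) -> list[str]:
    base = ["Raf", "MEK", "ERK"]
    return [base[t] if t < 3 else f"K{t + 1}" for t in range(n_tiers)]


def build_mapk_toy(params: CascadeParams | None = None) -> Network:
    """Build the toy MAPK-like cascade (see module docstring)."""
    p = params or CascadeParams()
    totals = {**_DEFAULT_TOTALS, **p.totals}
    rates = {k: v * p.rate_scales.get(k, 1.0) for k, v in _DEFAULT_RATES.items()}
    tiers = _tier_names(p.n_tiers)
    for t in tiers:
        totals.setdefault(t, 100.0)
        # one phosphatase per tier
    species: list[Species] = []
    reactions: list[Reaction] = []

    def sp(name, x0, comp):
        species.append(Species(name, x0, tuple(comp)))

    def rx(rid, lhs, rhs, k, tags=()):
        reactions.append(Reaction(rid, tuple(lhs), tuple(rhs), k, frozenset(tags)))

    def cycle(enzyme, substrate, product, rid, kcat, tags=(), comp=None):
        """E + S <-> ES -> E + P with the complex created on the fly."""
        es = f"{enzyme}_{substrate}"
        sp(es, 0.0, comp)
        rx(f"{rid}_bind", [(enzyme, 1), (substrate, 1)], [(es, 1)], rates["bind"], tags)
        rx(f"{rid}_unbind", [(es, 1)], [(enzyme, 1), (substrate, 1)], rates["unbind"], tags)
        rx(f"{rid}_cat", [(es, 1)], [(enzyme, 1), (product, 1)], kcat, tags)

    # --- GTPase cycle -----------------------------------------------------
    sp("RasGDP", totals["Ras"], ["KRAS"])
    sp("RasGTP", 0.0, ["KRAS"])
    sp("GEF", totals["GEF"], ["GEF"])
    sp("GAP", totals["GAP"], ["GAP"])
    cycle("GEF", "RasGDP", "RasGTP", "gef", rates["gef_cat"], comp=["GEF", "KRAS"])
    cycle(
        "GAP",
        "RasGTP",
        "RasGDP",
        "gap",
        rates["gap_cat"],
        tags=["deactivation:KRAS"],
        comp=["GAP", "KRAS"],
    )

    # --- kinase tiers -----------------------------------------------------
    upstream = "RasGTP"
    for t, name in enumerate(tiers):
        pase = f"Pase{t + 1}"
        totals.setdefault(pase, 50.0)
        sp(name, totals[name], [name])
        sp(pase, totals[pase], [pase])
        if p.double_phospho[t]:
            forms = [name, f"p{name}", f"pp{name}"]
        else:
            forms = [name, f"p{name}"]
        for f_ in forms[1:]:
            sp(f_, 0.0, [name])
        for i in range(len(forms) - 1):
            up_comp = [_base_protein(upstream, tiers), name]
            cycle(
                upstream,
                forms[i],
                forms[i + 1],
                f"{name.lower()}_act{i + 1}",
                rates["kinase_cat"],
                comp=up_comp,
            )
        for i in range(len(forms) - 1, 0, -1):
            cycle(
                pase,
                forms[i],
                forms[i - 1],
                f"{name.lower()}_deact{i}",
                rates["phosphatase_cat"],
                comp=[pase, name],
            )
        upstream = forms[-1]

    # --- PTEN-analog branch ----------------------------------------------
    sp("PTEN", totals["PTEN"], ["PTEN"])
    sp("Sub", totals["Sub"], ["SUB"])
    sp("SubP", 0.0, ["SUB"])
    cycle("PTEN", "Sub", "SubP", "pten", rates["pten_cat"], comp=["PTEN", "SUB"])
    rx("sub_recovery", [("SubP", 1)], [("Sub", 1)], rates["sub_recovery"])

    return Network(species, reactions)


def _base_protein(species_name: str, tiers: list[str]) -> str:
    for t in tiers:
        if species_name in (t, f"p{t}", f"pp{t}"):
            return t
    if species_name == "RasGTP":
        return "KRAS"
    return species_name


def build_reversible_pair(k_f: float, k_r: float, total: float) -> Network:
    """A <-> B with closed-form equilibrium
    (total*k_r/(k_f+k_r), total*k_f/(k_f+k_r))."""
    if k_f <= 0 or k_r <= 0 or total <= 0:
        raise ValueError("k_f, k_r, total must be > 0")
    return Network(
        [Species("A", total, ("A",)), Species("B", 0.0, ("A",))],
        [
            Reaction("fwd", (("A", 1),), (("B", 1),), k_f),
            Reaction("rev", (("B", 1),), (("A", 1),), k_r),
        ],
    )


def random_mass_action_network(n_species: int, n_reactions: int, seed: int) -> Network:
    """Seeded generator of closed uni/bimolecular networks.

    Species grow from a few monomers by isomerisation (new state, same
    composition) and complex formation (new species, merged composition);
    both moves are added as reversible pairs, so the implied per-monomer
    conservation laws hold by construction.  Leftover reaction budget is
    spent on parallel copies of existing reactions with fresh rates.
    """
    if n_species < 1 or n_reactions < 1:
        raise ValueError("n_species and n_reactions must be >= 1")
    rng = np.random.default_rng(seed)
    n_monomers = max(1, min(n_species, (n_species + 2) // 3))
    species: list[Species] = [
        Species(f"A{i}", float(rng.uniform(5.0, 50.0)), (f"M{i}",))
        for i in range(n_monomers)
    ]
    reactions: list[Reaction] = []

    def rate():
        return float(np.exp(rng.uniform(np.log(1e-3), np.log(1.0))))

    idx = n_monomers
    while len(species) < n_species:
        budget = n_reactions - len(reactions)
        bimolecular = len(species) >= 2 and rng.random() < 0.5
        if bimolecular:
            i, j = rng.choice(len(species), size=2, replace=True)
            a, b_ = species[int(i)], species[int(j)]
            comp = tuple(sorted(a.composition + b_.composition))
            new = Species(f"C{idx}", 0.0, comp)
            lhs = ((a.name, 2),) if a.name == b_.name else ((a.name, 1), (b_.name, 1))
            fwd = Reaction(f"r{len(reactions)}", lhs, ((new.name, 1),), rate())
            rev = Reaction(f"r{len(reactions) + 1}", ((new.name, 1),), lhs, rate())
        else:
            i = int(rng.integers(len(species)))
            a = species[i]
            new = Species(f"I{idx}", 0.0, a.composition)
            fwd = Reaction(f"r{len(reactions)}", ((a.name, 1),), ((new.name, 1),), rate())
            rev = Reaction(f"r{len(reactions) + 1}", ((new.name, 1),), ((a.name, 1),), rate())
        species.append(new)
        reactions.append(fwd)
        if budget >= 2 + 2 * (n_species - len(species)):
            reactions.append(rev)
        idx += 1
    # spend remaining budget on parallel copies (same stoichiometry, new k)
    while len(reactions) < n_reactions:
        if reactions:
            proto = reactions[int(rng.integers(len(reactions)))]
            reactions.append(
                Reaction(f"r{len(reactions)}", proto.reactants, proto.products, rate())
            )
        else:
            a = species[0]
            reactions.append(
                Reaction("r0", ((a.name, 1),), ((a.name, 1),), rate())
            )
    return Network(species, reactions[:n_reactions])


CRCRN_N_SPECIES = 419
CRCRN_N_REACTIONS = 850


def load_crcrn(directory: str | Path) -> Network:
    """Load the full colorectal-cancer network from a directory holding its
    interchange-format conversion (``network.crn`` or a single ``*.crn``).

    Warns when the species/reaction counts differ from the published
    419 / 850 or when no K-Ras de-activation tags are present.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise NetworkError("MISSING_FILES", f"{directory} is not a directory")
    candidate = directory / "network.crn"
    if not candidate.exists():
        found = sorted(directory.glob("*.crn"))
        if not found:
            raise NetworkError("MISSING_FILES", f"no .crn file in {directory}")
        candidate = found[0]
    net = load_network(candidate)
    if net.n != CRCRN_N_SPECIES or net.r != CRCRN_N_REACTIONS:
        warnings.warn(
            f"expected {CRCRN_N_SPECIES} species / {CRCRN_N_REACTIONS} reactions, "
            f"got {net.n} / {net.r}",
            stacklevel=2,
        )
    if not any(any(t.startswith("deactivation:KRAS") for t in rx.tags) for rx in net.reactions):
        warnings.warn("no deactivation:KRAS tags found", stacklevel=2)
    return net
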