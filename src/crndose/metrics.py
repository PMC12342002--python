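"""Effect profiles, the modified geometric mean G, and dose scans.

A mutation's global effect is the coordinate-wise relative difference
``delta_i = (x~_e,i - x_e,i) / x_e,i`` between the mutated and the
physiological equilibrium (defined because the physiological equilibrium is
strictly positive); a drug's effect ``d_i`` replaces the mutated by the
drug-loaded equilibrium.  ``delta_i = -1`` means the species is completely
shut down.  The scalar dosage index

    G(d) = (prod_i (|d_i| + 1e-6))**(1/n) - 1e-6

is a geometric mean modified to admit zero entries; it is zero iff d = 0
and grows with global distance from the physiological state, so the optimal
dose minimizes G over a concentration grid.  The magnitudes |d_i| are used
because a geometric mean of signed values is not well defined and G is read
as a distance to health.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservationBasis
from .dynamics import Trajectory
from .network import Network, NetworkError
from .perturb import DrugSpec, add_drug, extend_state

__all__ = [
    "EffectProfile",
    "DoseScanResult",
    "delta_profile",
    "top_variations",
    "geometric_index",
    "dose_scan_1d",
    "dose_scan_2d",
    "activated_fraction",
    "G_OFFSET",
]

G_OFFSET = 1e-6


@dataclass
class EffectProfile:
    """delta (mutation) or d (drug) relative-difference vector."""

    values: np.ndarray
    species: tuple[str, ...]
    role: str = "mutation_delta"  # or "drug_difference"
    reference: str = "physiological"
    comparison: str = ""

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.species.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"species": self.species, self.role: self.values})


def delta_profile(
    x_comp: np.ndarray,
    x_phys: np.ndarray,
    species: tuple[str, ...] | None = None,
    role: str = "mutation_delta",
) -> EffectProfile:
    """Relative difference (x_comp - x_phys) / x_phys, coordinate-wise.

    Raises ``ZERO_REFERENCE`` when any physiological concentration is zero;
    a different metric is needed in that regime.
    """
    x_comp = np.asarray(x_comp, dtype=float)
    x_phys = np.asarray(x_phys, dtype=float)
    if x_comp.shape != x_phys.shape:
        raise ValueError("equilibria have different dimensions")
    if np.any(x_phys <= 0):
        bad = int(np.argmin(x_phys))
        name = species[bad] if species else f"index {bad}"
        raise NetworkError("ZERO_REFERENCE", f"physiological concentration of {name} is 0")
    values = (x_comp - x_phys) / x_phys
    if species is None:
        species = tuple(f"x{i}" for i in range(len(values)))
    return EffectProfile(values, tuple(species), role=role)


def top_variations(
    x_comp: np.ndarray,
    x_phys: np.ndarray,
    species: tuple[str, ...],
    m: int = 10,
) -> pd.DataFrame:
    """The m species with the largest absolute concentration change,
    in decreasing order (ties keep species order), with their delta."""
    prof = delta_profile(x_comp, x_phys, species)
    diff = np.abs(np.asarray(x_comp, dtype=float) - np.asarray(x_phys, dtype=float))
    order = np.argsort(-diff, kind="stable")[:m]
    return pd.DataFrame(
        {
            "species": [species[i] for i in order],
            "abs_change_nM": diff[order],
            "delta": prof.values[order],
        }
    ).reset_index(drop=True)


def geometric_index(profile: EffectProfile | np.ndarray) -> float:
    """Modified geometric mean G of |d| with a 1e-6 offset, in log space."""
    d = profile.values if isinstance(profile, EffectProfile) else np.asarray(profile, dtype=float)
    if d.size == 0:
        raise ValueError("empty profile")
    return float(np.exp(np.mean(np.log(np.abs(d) + G_OFFSET))) - G_OFFSET)


@dataclass
class DoseScanResult:
    grid1: np.ndarray
    G_values: np.ndarray  # shape (len(grid1),) or (len(grid1), len(grid2))
    argmin: tuple[float, ...]
    grid2: np.ndarray | None = None
    profiles_at: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    @property
    def G_min(self) -> float:
        return float(np.nanmin(self.G_values))

    def to_frame(self) -> pd.DataFrame:
        if self.grid2 is None:
            return pd.DataFrame({"dose": self.grid1, "G": self.G_values})
        rows = []
        for i, a in enumerate(self.grid1):
            for j, b in enumerate(self.grid2):
                rows.append((a, b, self.G_values[i, j]))
        return pd.DataFrame(rows, columns=["dose1", "dose2", "G"])


def _restrict(net_aug: Network, x_aug: np.ndarray, original: tuple[str, ...]) -> np.ndarray:
    return np.array([x_aug[net_aug.index(name)] for name in original])


def _profile_for_doses(
    net_mut: Network,
    x_tilde_e: np.ndarray,
    x_phys_e: np.ndarray,
    drugs: list[DrugSpec],
    seed: int,
    solver_kwargs: dict,
) -> EffectProfile:
    """d-profile on the original species for a concurrent set of doses.

    Zero-dose drugs are skipped entirely, so zero rows/columns of a scan
    coincide exactly with lower-dimensional scans.
    """
    active = [d for d in drugs if d.c0 > 0]
    names = net_mut.species_names
    if not active:
        return delta_profile(x_tilde_e, x_phys_e, names, role="drug_difference")
    net_aug = net_mut
    x = np.asarray(x_tilde_e, dtype=float)
    for spec in active:
        bare = DrugSpec(
            name=spec.name,
            mechanism=spec.mechanism,
            targets=spec.targets,
            k_on=spec.k_on,
            k_off=spec.k_off,
            c0=spec.c0,
        )
        prev = net_aug
        net_aug = add_drug(net_aug, bare)
        x = extend_state(net_aug, prev, x, bare)
    from .conservation import find_conservation_laws
    from .equilibrium import solve_equilibrium

    basis = find_conservation_laws(net_aug)
    res = solve_equilibrium(net_aug, basis, x, seed=seed, **solver_kwargs)
    if not res.converged:
        raise RuntimeError(
            f"equilibrium failed at doses {[d.c0 for d in active]} (residual {res.residual:.2e})"
        )
    x_d = _restrict(net_aug, res.x_e, names)
    return delta_profile(x_d, x_phys_e, names, role="drug_difference")


def dose_scan_1d(
    net_mut: Network,
    x_tilde_e: np.ndarray,
    x_phys_e: np.ndarray,
    drug: DrugSpec,
    grid: np.ndarray,
    seed: int = 0,
    keep_profiles: tuple[float, ...] = (),
    **solver_kwargs,
) -> DoseScanResult:
    """G(c) over a dose grid; the argmin picks the best initial drug
    concentration (smallest dose on ties)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("grid must be non-empty and non-negative")
    G = np.full(grid.shape, np.nan)
    profiles = {}
    failures = []
    for idx, c in enumerate(grid):
        spec = DrugSpec(
            name=drug.name,
            mechanism=drug.mechanism,
            targets=drug.targets,
            k_on=drug.k_on,
            k_off=drug.k_off,
            c0=float(c),
        )
        try:
            prof = _profile_for_doses(
                net_mut, x_tilde_e, x_phys_e, [spec], seed, solver_kwargs
            )
        except (RuntimeError, NetworkError) as e:
            failures.append((float(c), str(e)))
            continue
        G[idx] = geometric_index(prof)
        if float(c) in keep_profiles:
            profiles[float(c)] = prof
    if np.all(np.isnan(G)):
        raise RuntimeError("every dose failed")
    best = int(np.nanargmin(G))  # nanargmin returns the first (smallest dose) tie
    return DoseScanResult(grid, G, (float(grid[best]),), None, profiles, failures)


def dose_scan_2d(
    net_mut: Network,
    x_tilde_e: np.ndarray,
    x_phys_e: np.ndarray,
    drugA: DrugSpec,
    drugB: DrugSpec,
    gridA: np.ndarray,
    gridB: np.ndarray,
    seed: int = 0,
    **solver_kwargs,
) -> DoseScanResult:
    """G over the product grid, both drugs given concurrently.

    The argmin uses lexicographic smallest-dose tie-breaking, and the
    zero-dose row/column reproduces the corresponding 1-D scan exactly.
    """
    gridA = np.asarray(gridA, dtype=float)
    gridB = np.asarray(gridB, dtype=float)
    if gridA.size == 0 or gridB.size == 0:
        raise ValueError("grids must be non-empty")
    G = np.full((len(gridA), len(gridB)), np.nan)
    failures = []
    for i, ca in enumerate(gridA):
        for j, cb in enumerate(gridB):
            specs = []
            for spec, c in ((drugA, ca), (drugB, cb)):
                specs.append(
                    DrugSpec(
                        name=spec.name,
                        mechanism=spec.mechanism,
                        targets=spec.targets,
                        k_on=spec.k_on,
                        k_off=spec.k_off,
                        c0=float(c),
                    )
                )
            try:
                prof = _profile_for_doses(
                    net_mut, x_tilde_e, x_phys_e, specs, seed, solver_kwargs
                )
            except (RuntimeError, NetworkError) as e:
                failures.append(((float(ca), float(cb)), str(e)))
                continue
            G[i, j] = geometric_index(prof)
    if np.all(np.isnan(G)):
        raise RuntimeError("every dose pair failed")
    flat = np.nanargmin(G)
    i, j = np.unravel_index(flat, G.shape)
    return DoseScanResult(
        gridA, G, (float(gridA[i]), float(gridB[j])), gridB, {}, failures
    )


def activated_fraction(
    traj: Trajectory,
    active_species: str,
    basis: ConservationBasis,
    moiety: str,
) -> np.ndarray:
    """Time series active(t) / moiety_total, using the conservation row
    whose elemental species is ``moiety`` evaluated at the initial state."""
    row = basis.row_for_elemental(moiety)
    order = [traj.species.index(name) for name in basis.species]
    total = float(basis.N[row] @ traj.states[0][order])
    if total <= 0:
        raise NetworkError("ZERO_MOIETY", f"total of {moiety} is zero")
    return traj[active_species] / total
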