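"""Equilibria on stoichiometric compatibility classes by constrained
root finding.

The steady state on the class of ``x0`` solves the square system

    F(x) = [ (S v(x, k))_i  for i not elemental ;  N x - N x0 ] = 0,

where the p kinetic rows of the elemental species are deleted — each is a
rational combination of the retained rows given ``N S = 0`` — and replaced
by the p conservation constraints.  The solver is a damped projected Newton
iteration on ``0.5 ||F||^2`` with projection onto the non-negative orthant,
a gradient-descent fallback on Newton stagnation, and seeded multi-start
from randomized points of the compatibility class.  Under the global
stability condition each class carries a unique equilibrium, so every start
should land on the same root; multi-start doubles as an empirical check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conservation import ConservationBasis
from .dynamics import _flux_jacobian, _fluxes_unchecked
from .network import Network

__all__ = ["EquilibriumResult", "solve_equilibrium", "row_reduction_choice"]


@dataclass
class EquilibriumResult:
    """An equilibrium state with convergence diagnostics.

    ``x_e`` is the physiological, mutated or drug-loaded equilibrium
    depending on which network it was computed for.
    """

    x_e: np.ndarray
    residual: float  # ||F(x_e)||_2
    iterations: int
    method: str  # "nlpc" | "ode"
    converged: bool
    class_residual: float  # ||N x_e - N x0||_inf
    horizon: float | None = None
    restarts_used: int = 0
    message: str = ""

    def __getitem__(self, idx):
        return self.x_e[idx]


def row_reduction_choice(net: Network, basis: ConservationBasis) -> list[int]:
    """Kinetic rows to delete: the p elemental-species rows.

    Given ``N S = 0`` and the identity submatrix on the elemental columns,
    each elemental row of ``S v`` equals minus a non-negative combination of
    the other rows in its moiety, so deleting it loses nothing; stacking the
    p conservation rows restores a square n x n system.
    """
    if basis.p == 0:
        return []
    if not basis.weakly_elemented:
        raise ValueError("row reduction requires a weakly elemented basis")
    return sorted(basis.elemental_index)


def _sample_on_class(
    basis: ConservationBasis, x0: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """A randomized state near the compatibility class of x0.

    Each moiety total is redistributed over the moiety's species by a
    Dirichlet draw; species shared between moieties receive the mean of
    their draws, and the result is projected back onto {N x = b} (affine
    least squares) and clipped at zero.
    """
    n = basis.n
    N = basis.N
    x = np.zeros(n)
    counts = np.zeros(n)
    for l in range(basis.p):
        sup = np.nonzero(N[l] > 0)[0]
        w = rng.dirichlet(np.ones(len(sup)))
        x[sup] += b[l] * w / N[l, sup]
        counts[sup] += 1
    free = counts == 0
    x[~free] /= counts[~free]
    x[free] = x0[free] * np.exp(rng.normal(0.0, 0.5, size=int(free.sum())))
    if basis.p:
        for _ in range(3):
            corr, *_ = np.linalg.lstsq(N, b - N @ x, rcond=None)
            x = np.maximum(x + corr, 0.0)
    return x


def solve_equilibrium(
    net: Network,
    basis: ConservationBasis,
    x0: np.ndarray,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 200,
    restarts: int = 10,
    randomize_start: bool = False,
) -> EquilibriumResult:
    """Equilibrium on the compatibility class of ``x0`` (projected Newton).

    Parameters
    ----------
    basis
        Weakly elemented conservation basis of ``net`` (or empty, p = 0).
    x0
        Non-negative state fixing the conserved totals; also the first
        Newton start.
    seed
        Seeds the Dirichlet restarts; the returned root is start-independent
        when the global stability condition holds.  With
        ``randomize_start=True`` even the first iterate is sampled from the
        class (used to probe equilibrium uniqueness empirically).
    tol
        Convergence threshold on ``||F||_inf / (1 + ||x||_inf)``.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (net.n,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({net.n},)")
    if np.any(x0 < 0):
        raise ValueError("x0 must be non-negative")
    drop = row_reduction_choice(net, basis)
    keep = np.array([i for i in range(net.n) if i not in set(drop)], dtype=int)
    S = net.S.astype(float)
    N = basis.N if basis.p else np.zeros((0, net.n))
    b = N @ x0 if basis.p else np.zeros(0)

    def F(x):
        sv = S @ _fluxes_unchecked(net, x)
        return np.concatenate([sv[keep], N @ x - b])

    def J(x):
        Jfull = S @ _flux_jacobian(net, x)
        return np.vstack([Jfull[keep], N])

    rng = np.random.default_rng(seed)
    best: EquilibriumResult | None = None
    total_starts = 1 + max(0, restarts)
    for start_no in range(total_starts):
        x = (
            x0.copy()
            if start_no == 0 and not randomize_start
            else _sample_on_class(basis, x0, b, rng)
        )
        res = _newton_projected(F, J, x, tol, max_iter)
        res.restarts_used = start_no
        res.class_residual = (
            float(np.linalg.norm(N @ res.x_e - b, np.inf)) if basis.p else 0.0
        )
        res.method = "nlpc"
        if res.converged:
            jac = J(res.x_e)
            if np.linalg.matrix_rank(jac) < net.n:
                res.message = (
                    "reduced Jacobian rank-deficient at the solution; "
                    "possible non-isolated equilibrium"
                )
            return res
        if best is None or res.residual < best.residual:
            best = res
    assert best is not None
    best.message = best.message or f"no convergence after {total_starts} starts"
    return best


def _newton_projected(F, J, x, tol, max_iter) -> EquilibriumResult:
    def merit(Fx):
        return 0.5 * float(Fx @ Fx)

    Fx = F(x)
    f = merit(Fx)
    it = 0
    while it < max_iter:
        scale = 1.0 + float(np.linalg.norm(x, np.inf))
        if np.linalg.norm(Fx, np.inf) < tol * scale:
            return EquilibriumResult(
                x_e=x,
                residual=float(np.linalg.norm(Fx)),
                iterations=it,
                method="nlpc",
                converged=True,
                class_residual=0.0,
            )
        it += 1
        Jx = J(x)
        try:
            d = np.linalg.solve(Jx, -Fx)
        except np.linalg.LinAlgError:
            d, *_ = np.linalg.lstsq(Jx, -Fx, rcond=None)
        accepted = False
        t = 1.0
        for _ in range(40):
            xn = np.maximum(x + t * d, 0.0)
            Fn = F(xn)
            fn = merit(Fn)
            if fn <= f * (1.0 - 1e-4 * t):
                x, Fx, f = xn, Fn, fn
                accepted = True
                break
            t *= 0.5
        if accepted:
            continue
        # gradient-descent fallback on 0.5 ||F||^2 with backtracking
        g = Jx.T @ Fx
        gn2 = float(g @ g)
        if gn2 == 0.0:
            break
        t = f / gn2
        for _ in range(50):
            xn = np.maximum(x - t * g, 0.0)
            Fn = F(xn)
            fn = merit(Fn)
            if fn <= f - 1e-4 * t * gn2:
                x, Fx, f = xn, Fn, fn
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break  # stagnation: hand control back for a restart
    return EquilibriumResult(
        x_e=x,
        residual=float(np.linalg.norm(Fx)),
        iterations=it,
        method="nlpc",
        converged=False,
        class_residual=0.0,
    )
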