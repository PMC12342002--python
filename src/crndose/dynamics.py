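"""Mass-action dynamics: fluxes, ODE right-hand side, Jacobian, integration.

The dynamics of a network is ``xdot = S v(x, k)`` with flux
``v_j = k_j * prod_i x_i**a_ij`` (a_ij = reactant coefficient).  Time is in
seconds throughout; the reporting layer converts to minutes.  Signalling
cascades are stiff (binding at ~1e-3 /nM/s against catalysis at ~1 /s), so
the default integrator is BDF with the analytic Jacobian and tight
tolerances (rtol 1e-8, atol 1e-12 nM) — equilibrium-difference profiles
amplify small absolute errors for low-abundance species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import Network, NetworkError

__all__ = [
    "AdministrationEvent",
    "Trajectory",
    "reaction_fluxes",
    "ode_rhs",
    "jacobian",
    "simulate",
    "simulate_to_equilibrium",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12


@dataclass(frozen=True)
class AdministrationEvent:
    """Instantaneous bolus: at ``time`` (s) the named species' concentration
    is incremented by ``amount`` (nM)."""

    time: float
    species: str
    amount: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.amount <= 0:
            raise ValueError("event amount must be > 0")


@dataclass
class Trajectory:
    times: np.ndarray  # seconds, strictly increasing
    states: np.ndarray  # len(times) x n, nM
    species: tuple[str, ...]
    events: tuple[AdministrationEvent, ...] = ()

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_csv(self, path: str | Path) -> None:
        header = ["time_s", *self.species]
        lines = []
        for ev in self.events:
            lines.append(f"# event t={ev.time!r}s {ev.species} +{ev.amount!r}nM")
        lines.append(",".join(header))
        for t, row in zip(self.times, self.states):
            lines.append(",".join([repr(float(t))] + [repr(float(v)) for v in row]))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _check_state(net: Network, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n,):
        raise ValueError(f"state has shape {x.shape}, expected ({net.n},)")
    if np.any(x < 0):
        raise ValueError("negative concentration in state vector")
    return x


def reaction_fluxes(net: Network, x: np.ndarray) -> np.ndarray:
    """Mass-action fluxes v_j = k_j * prod_i x_i**a_ij (zeroth order: k_j)."""
    x = _check_state(net, x)
    A = net.reactant_matrix
    # 0**0 == 1, so species outside a reaction contribute a unit factor
    with np.errstate(divide="ignore"):
        v = net.k * np.prod(x[:, None] ** A, axis=0)
    return v


def _fluxes_unchecked(net: Network, x: np.ndarray) -> np.ndarray:
    A = net.reactant_matrix
    xc = np.maximum(x, 0.0)
    return net.k * np.prod(xc[:, None] ** A, axis=0)


def ode_rhs(net: Network, x: np.ndarray) -> np.ndarray:
    """Right-hand side S v(x, k)."""
    return net.S @ reaction_fluxes(net, x)


def jacobian(net: Network, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of S v(x, k) with respect to x (n x n)."""
    x = np.asarray(x, dtype=float)
    return net.S @ _flux_jacobian(net, x)


def _flux_jacobian(net: Network, x: np.ndarray) -> np.ndarray:
    """r x n matrix dv_j/dx_i, careful at x_i = 0."""
    A = net.reactant_matrix
    n, r = A.shape
    xc = np.maximum(x, 0.0)
    dv = np.zeros((r, n))
    for j in range(r):
        idx = np.nonzero(A[:, j])[0]
        kj = net.k[j]
        for i in idx:
            a = A[i, j]
            term = kj * a
            # x_i ** (a-1)
            if a > 1:
                term *= xc[i] ** (a - 1)
            for i2 in idx:
                if i2 != i:
                    term *= xc[i2] ** A[i2, j]
            dv[j, i] = term
    return dv


def _integrate_segment(net, x, t0, t1, t_eval, rtol, atol, method):
    def rhs(t, y):
        return net.S @ _fluxes_unchecked(net, y)

    def jac(t, y):
        return net.S @ _flux_jacobian(net, y)

    sol = solve_ivp(
        rhs,
        (t0, t1),
        x,
        method=method,
        jac=jac,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if len(sol.t) else t0:.3g} s: {sol.message}"
        )
    return sol


def simulate(
    net: Network,
    x0: np.ndarray,
    t_grid: Sequence[float],
    events: Sequence[AdministrationEvent] = (),
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the Cauchy problem on ``t_grid``, applying bolus events.

    At each event time integration halts, the named species is incremented,
    and integration resumes; between events the moiety totals ``N x`` are
    conserved to integrator tolerance.
    """
    x = _check_state(net, x0).copy()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    events = tuple(sorted(events, key=lambda e: e.time))
    for ev in events:
        if ev.species not in net:
            raise NetworkError("UNKNOWN_SPECIES", ev.species)

    t0 = t_grid[0]
    out_t: list[float] = []
    out_x: list[np.ndarray] = []
    # events at or before the start apply immediately
    pending = []
    for ev in events:
        if ev.time <= t0:
            x[net.index(ev.species)] += ev.amount
        else:
            pending.append(ev)

    cur_t = t0
    remaining = t_grid
    for ev in pending + [None]:
        seg_end = t_grid[-1] if ev is None else min(ev.time, t_grid[-1])
        mask = (remaining > cur_t) & (remaining <= seg_end)
        te = remaining[mask]
        if cur_t == t0 and t_grid[0] >= cur_t and (not out_t):
            out_t.append(cur_t)
            out_x.append(x.copy())
        if seg_end > cur_t:
            te_full = te if len(te) and te[-1] == seg_end else np.append(te, seg_end)
            sol = _integrate_segment(net, x, cur_t, seg_end, te_full, rtol, atol, method)
            for tt, col in zip(sol.t, sol.y.T):
                if tt in te:
                    out_t.append(tt)
                    out_x.append(np.maximum(col, 0.0))
            x = np.maximum(sol.y[:, -1], 0.0)
            cur_t = seg_end
        if ev is not None and ev.time <= t_grid[-1]:
            x[net.index(ev.species)] += ev.amount
        if cur_t >= t_grid[-1]:
            break

    times = np.array(out_t)
    states = np.vstack(out_x)
    return Trajectory(times, states, net.species_names, events)


def simulate_to_equilibrium(
    net: Network,
    x0: np.ndarray,
    tol_eq: float = 1e-10,
    t_start: float = 1e2,
    max_horizon: float = 1e9,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "BDF",
):
    """Integrate with a geometrically growing horizon until the flux balance
    ``||S v(x)||_inf < tol_eq * (1 + ||x||_inf)`` holds at two successive
    checkpoints (doubling horizons), guarding against plateaus on slow
    transients.  Returns an :class:`~crndose.equilibrium.EquilibriumResult`
    with ``method="ode"``.
    """
    from .equilibrium import EquilibriumResult  # local import avoids a cycle

    x = _check_state(net, x0).copy()
    t = 0.0
    horizon = t_start
    hits = 0
    n_seg = 0
    while t < max_horizon:
        sol = _integrate_segment(net, x, t, horizon, np.array([horizon]), rtol, atol, method)
        x = np.maximum(sol.y[:, -1], 0.0)
        t = horizon
        n_seg += 1
        res = np.linalg.norm(net.S @ _fluxes_unchecked(net, x), np.inf)
        if res < tol_eq * (1.0 + np.linalg.norm(x, np.inf)):
            hits += 1
            if hits >= 2:
                return EquilibriumResult(
                    x_e=x,
                    residual=float(np.linalg.norm(net.S @ _fluxes_unchecked(net, x))),
                    iterations=n_seg,
                    method="ode",
                    converged=True,
                    class_residual=0.0,
                    horizon=t,
                )
        else:
            hits = 0
        horizon *= 2.0
    return EquilibriumResult(
        x_e=x,
        residual=float(np.linalg.norm(net.S @ _fluxes_unchecked(net, x))),
        iterations=n_seg,
        method="ode",
        converged=False,
        class_residual=0.0,
        horizon=t,
        message="horizon exhausted; possible oscillation or slow mode",
    )
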