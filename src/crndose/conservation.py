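"""Moiety conservation laws and stoichiometric compatibility classes.

A conservation law is a semi-positive vector ``y >= 0`` with ``S^T y = 0``;
the weighted total ``y . x(t)`` is then constant along every trajectory.
The rows of the conservation matrix ``N`` (p x n) span the semi-positive
part of the left null space of ``S``.  ``N`` is *weakly elemented* when it
contains a p x p identity submatrix, i.e. each law has an *elemental*
species that appears in no other law; the conserved totals can then be read
off one species per moiety.

The basis is computed exactly: a rational null-space basis of ``S^T``
(sympy), then the extreme rays of the cone ``{y >= 0 : S^T y = 0}`` by the
double-description method in Fraction arithmetic.  ``N . S = 0`` therefore
holds exactly, not merely to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np
import sympy as sp

from .network import Network, NetworkError

__all__ = [
    "ConservationBasis",
    "find_conservation_laws",
    "compatibility_residual",
]


@dataclass
class ConservationBasis:
    """Semi-positive conservation matrix bound to a species ordering."""

    rows: tuple[tuple[Fraction, ...], ...]  # p x n, exact
    species: tuple[str, ...]
    elemental_index: tuple[int, ...]
    weakly_elemented: bool
    warnings: tuple[str, ...] = ()
    _N: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def p(self) -> int:
        return len(self.rows)

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def N(self) -> np.ndarray:
        """Float view of the exact matrix (p x n)."""
        if self._N is None:
            self._N = np.array(
                [[float(v) for v in row] for row in self.rows], dtype=float
            ).reshape(self.p, self.n)
        return self._N

    def totals(self, x0: np.ndarray) -> np.ndarray:
        """Conserved totals N . x0 of the compatibility class of x0."""
        return self.N @ np.asarray(x0, dtype=float)

    def row_for_elemental(self, name: str) -> int:
        """Index of the law whose elemental species is ``name``."""
        idx = self.species.index(name)
        for l, j in enumerate(self.elemental_index):
            if j == idx:
                return l
        raise NetworkError("NOT_ELEMENTAL", name)


# ---------------------------------------------------------------------------
# exact linear algebra helpers (Fractions)


def _rank(rows: list[tuple[Fraction, ...]]) -> int:
    m = [list(r) for r in rows]
    rank = 0
    cols = len(m[0]) if m else 0
    for c in range(cols):
        piv = None
        for i in range(rank, len(m)):
            if m[i][c] != 0:
                piv = i
                break
        if piv is None:
            continue
        m[rank], m[piv] = m[piv], m[rank]
        pv = m[rank][c]
        for i in range(len(m)):
            if i != rank and m[i][c] != 0:
                f = m[i][c] / pv
                m[i] = [a - f * b for a, b in zip(m[i], m[rank])]
        rank += 1
        if rank == len(m):
            break
    return rank


def _invert(mat: list[list[Fraction]]) -> list[list[Fraction]]:
    q = len(mat)
    aug = [list(row) + [Fraction(int(i == j)) for j in range(q)] for i, row in enumerate(mat)]
    for c in range(q):
        piv = next(i for i in range(c, q) if aug[i][c] != 0)
        aug[c], aug[piv] = aug[piv], aug[c]
        pv = aug[c][c]
        aug[c] = [a / pv for a in aug[c]]
        for i in range(q):
            if i != c and aug[i][c] != 0:
                f = aug[i][c]
                aug[i] = [a - f * b for a, b in zip(aug[i], aug[c])]
    return [row[q:] for row in aug]


def _primitive(vec: tuple[Fraction, ...]) -> tuple[Fraction, ...]:
    """Scale a rational ray to a primitive integer vector."""
    denoms = [v.denominator for v in vec]
    L = 1
    for d in denoms:
        L = L * d // gcd(L, d)
    ints = [int(v * L) for v in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g == 0:
        return vec
    return tuple(Fraction(v, g) for v in ints)


def _extreme_rays(A: list[tuple[Fraction, ...]]) -> list[tuple[Fraction, ...]]:
    """Extreme rays of the pointed cone {a in R^q : A a >= 0}, rank(A) = q.

    Incremental double description: start from a simplicial cone given by q
    linearly independent inequalities, then cut with the remaining ones.
    Adjacency is decided combinatorially via active-set inclusion.
    """
    q = len(A[0])
    # choose q independent starting rows
    base: list[int] = []
    rows: list[tuple[Fraction, ...]] = []
    for i, row in enumerate(A):
        if _rank(rows + [row]) > len(rows):
            base.append(i)
            rows.append(row)
            if len(rows) == q:
                break
    if len(rows) < q:
        raise ValueError("constraint matrix not full rank; cone not pointed")
    Binv = _invert([list(A[i]) for i in base])
    rays = [tuple(Binv[r][j] for r in range(q)) for j in range(q)]
    rays = [_primitive(r) for r in rays]
    processed = list(base)

    def dot(row, ray):
        return sum(a * b for a, b in zip(row, ray))

    for i, row in enumerate(A):
        if i in base:
            continue
        vals = [dot(row, r) for r in rays]
        plus = [(r, v) for r, v in zip(rays, vals) if v > 0]
        zero = [r for r, v in zip(rays, vals) if v == 0]
        minus = [(r, v) for r, v in zip(rays, vals) if v < 0]
        if not minus:
            processed.append(i)
            continue
        if not plus and not zero:
            return []
        active = {
            r: frozenset(j for j in processed if dot(A[j], r) == 0) for r in rays
        }
        new: list[tuple[Fraction, ...]] = []
        for rp, vp in plus:
            for rm, vm in minus:
                common = active[rp] & active[rm]
                # adjacency: no third ray's active set contains the common set
                adjacent = True
                for r3 in rays:
                    if r3 is rp or r3 is rm:
                        continue
                    if common <= active[r3]:
                        adjacent = False
                        break
                if adjacent:
                    cand = tuple(vp * b - vm * a for a, b in zip(rp, rm))
                    new.append(_primitive(cand))
        seen = set()
        merged = []
        for r in [r for r, _ in plus] + zero + new:
            if r not in seen:
                seen.add(r)
                merged.append(r)
        rays = merged
        processed.append(i)
    return rays


# ---------------------------------------------------------------------------
# public operations


def _exact_NS_check(rows, net: Network) -> None:
    Sx = net.S
    for row in rows:
        for j in range(net.r):
            total = sum(row[i] * int(Sx[i, j]) for i in range(net.n))
            if total != 0:
                raise NetworkError(
                    "BAD_CONSERVATION", f"declared row does not annihilate reaction column {j}"
                )


def _elementals(rows) -> tuple[tuple[int, ...], bool, tuple[tuple[Fraction, ...], ...]]:
    """Find one elemental species per row and rescale rows to make the
    corresponding submatrix the identity.  Lowest species index wins."""
    p = len(rows)
    n = len(rows[0]) if rows else 0
    chosen: list[int] = []
    scaled: list[tuple[Fraction, ...]] = []
    complete = True
    for l in range(p):
        cand = None
        for j in range(n):
            if rows[l][j] > 0 and all(rows[m][j] == 0 for m in range(p) if m != l):
                cand = j
                break
        if cand is None:
            complete = False
            scaled.append(rows[l])
        else:
            chosen.append(cand)
            pv = rows[l][cand]
            scaled.append(tuple(v / pv for v in rows[l]))
    return tuple(chosen), complete and p > 0, tuple(scaled)


def find_conservation_laws(net: Network) -> ConservationBasis:
    """Extract a semi-positive conservation basis for ``net``.

    Pre-declared CONSERVATION rows, when present, are verified
    (``N . S = 0`` exactly, entries >= 0) and used as-is; otherwise the
    extreme rays of the semi-positive left-kernel cone are computed.
    A warning is recorded when the left null space contains directions that
    no semi-positive combination can represent (p < dim ker S^T).
    """
    names = net.species_names
    warnings: list[str] = []

    if net.declared_conservations:
        rows = []
        for con in net.declared_conservations:
            row = [Fraction(0)] * net.n
            for coeff, spname in con.terms:
                if coeff < 0:
                    raise NetworkError("BAD_CONSERVATION", f"{con.name}: negative coefficient")
                row[net.index(spname)] = coeff
            rows.append(tuple(row))
        _exact_NS_check(rows, net)
        if _rank(rows) < len(rows):
            raise NetworkError("BAD_CONSERVATION", "declared rows are linearly dependent")
    else:
        ST = sp.Matrix(net.S).T
        null = ST.nullspace()
        q = len(null)
        if q == 0:
            return ConservationBasis((), names, (), False, ())
        # cone {alpha : K alpha >= 0} in kernel coordinates, K = n x q
        K = [
            tuple(Fraction(null[c][i, 0]) for c in range(q))
            for i in range(net.n)
        ]
        rays = _extreme_rays(K)
        rows = []
        for ray in rays:
            y = tuple(sum(K[i][c] * ray[c] for c in range(q)) for i in range(net.n))
            rows.append(_primitive(y))
        rows.sort(key=lambda r: ([i for i, v in enumerate(r) if v != 0], r))
        if (_rank(rows) if rows else 0) < q:
            warnings.append(
                "left null space has directions not representable semi-positively"
            )
        if not rows:
            return ConservationBasis((), names, (), False, tuple(warnings))
        if _rank(rows) < len(rows):
            # keep a maximal independent subset, preferring small supports
            kept: list[tuple[Fraction, ...]] = []
            for row in sorted(rows, key=lambda r: sum(1 for v in r if v != 0)):
                if _rank(kept + [row]) > len(kept):
                    kept.append(row)
            warnings.append("extreme rays were linearly dependent; kept an independent subset")
            rows = kept

    elemental, weak, scaled = _elementals(tuple(rows))
    return ConservationBasis(scaled, names, elemental, weak, tuple(warnings))


def compatibility_residual(
    basis: ConservationBasis, x: np.ndarray, x0: np.ndarray
) -> np.ndarray:
    """``N x - N x0``: the zero vector iff ``x`` lies on the stoichiometric
    compatibility class of ``x0``."""
    x = np.asarray(x, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if x.shape != (basis.n,) or x0.shape != (basis.n,):
        raise ValueError(
            f"state dimension mismatch: basis expects {basis.n}, got {x.shape} / {x0.shape}"
        )
    return basis.N @ x - basis.N @ x0
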