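"""Mass-action reaction networks: the static model.

A :class:`Network` holds an ordered list of species (with initial
concentrations in nM), an ordered list of mass-action reactions (integer
stoichiometry, rate constant ``k``), and the n x r stoichiometric matrix
``S`` with ``S[i, j] = (product coefficient of species i in reaction j)
- (reactant coefficient)``.  The associated dynamics is ``xdot = S v(x, k)``
with mass-action fluxes ``v_j = k_j * prod_i x_i**a_ij``.

Networks are read and written in a line-oriented UTF-8 text format::

    SPECIES <name> <x0_nM> [composition=P1+P2+...]
    REACTION <id> <c> <sp> + ... -> <c> <sp> + ... ; k=<float> [; tags=t1,t2]
    CONSERVATION <name> <coeff> <species> [+ <coeff> <species> ...]

An empty reactant or product side is written ``0`` (zeroth-order source /
degradation sink).  ``#`` starts a comment.  CONSERVATION lines are optional,
pre-declared moiety totals that are verified on load.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Species",
    "Reaction",
    "Network",
    "NetworkError",
    "ParseError",
    "ValidationReport",
    "load_network",
    "loads_network",
    "save_network",
    "dumps_network",
    "validate_network",
    "species_table",
    "reaction_table",
]


class NetworkError(ValueError):
    """A network violates a structural invariant.

    Carries a short machine-readable ``code`` (e.g. ``UNKNOWN_SPECIES``).
    """

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


class ParseError(NetworkError):
    def __init__(self, message: str, line: int | None = None):
        loc = f" (line {line})" if line is not None else ""
        super().__init__("PARSE_ERROR", message + loc)
        self.line = line


@dataclass(frozen=True)
class Species:
    """A chemical species.

    ``composition`` is the multiset of base-protein names making up the
    species (e.g. a kinase-substrate complex lists both proteins); it drives
    loss-of-function projections, which zero a protein and every compound
    containing it.
    """

    name: str
    x0: float = 0.0
    composition: tuple[str, ...] | None = None
    phospho_state: str | None = None

    def __post_init__(self):
        if not self.name or any(c.isspace() for c in self.name):
            raise NetworkError("BAD_NAME", f"invalid species name {self.name!r}")
        if self.x0 < 0:
            raise NetworkError("NEGATIVE_X0", f"{self.name}: x0 = {self.x0} < 0")
        if self.composition is not None:
            if len(self.composition) == 0:
                raise NetworkError("EMPTY_COMPOSITION", self.name)
            object.__setattr__(self, "composition", tuple(self.composition))

    def contains(self, protein: str) -> bool:
        """Whether ``protein`` occurs in this species' composition.

        Species without composition metadata are treated as the bare
        protein named by their own name.
        """
        comp = self.composition if self.composition is not None else (self.name,)
        return protein in comp


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction.

    Reversible pairs are written as two reactions.  ``k`` has units
    nM^(1-order) s^-1 where order is the sum of reactant coefficients.
    ``tags`` mark roles used by the perturbation layer, with the dialect
    ``deactivation:<GENE>``, ``drug:<NAME>`` and ``degradation``.
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    k: float
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple((s, int(c)) for s, c in self.reactants))
        object.__setattr__(self, "products", tuple((s, int(c)) for s, c in self.products))
        object.__setattr__(self, "tags", frozenset(self.tags))
        if self.k <= 0:
            raise NetworkError("NONPOSITIVE_RATE", f"{self.id}: k = {self.k}")
        if not self.reactants and not self.products:
            raise NetworkError("EMPTY_REACTION", self.id)
        for side in (self.reactants, self.products):
            for name, c in side:
                if c <= 0:
                    raise NetworkError(
                        "BAD_COEFFICIENT", f"{self.id}: coefficient {c} for {name}"
                    )

    @property
    def order(self) -> int:
        return sum(c for _, c in self.reactants)

    def equation(self) -> str:
        def side(terms):
            if not terms:
                return "0"
            return " + ".join(f"{c} {s}" if c != 1 else s for s, c in terms)

        return f"{side(self.reactants)} -> {side(self.products)}"


@dataclass(frozen=True)
class DeclaredConservation:
    """A moiety total pre-declared in the network file."""

    name: str
    terms: tuple[tuple[Fraction, str], ...]  # (coefficient, species)


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


class Network:
    """An immutable-by-convention mass-action network.

    Parameters
    ----------
    species, reactions
        Ordered sequences; order is preserved and defines the row/column
        order of ``S``.
    declared_conservations
        Optional pre-declared conservation rows (verified elsewhere).
    check
        When True (default) referential integrity is enforced at
        construction; ``check=False`` defers to :func:`validate_network`.
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        declared_conservations: Sequence[DeclaredConservation] = (),
        check: bool = True,
    ):
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.declared_conservations: tuple[DeclaredConservation, ...] = tuple(
            declared_conservations
        )
        self._index = {}
        for i, sp in enumerate(self.species):
            if sp.name in self._index:
                raise NetworkError("DUPLICATE_SPECIES", sp.name)
            self._index[sp.name] = i
        seen = set()
        for rx in self.reactions:
            if rx.id in seen:
                raise NetworkError("DUPLICATE_REACTION", rx.id)
            seen.add(rx.id)
        if check:
            report = validate_network(self)
            if not report.ok:
                code, msg = report.errors[0]
                raise NetworkError(code, msg)
        self._S: np.ndarray | None = None
        self._A: np.ndarray | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise NetworkError("UNKNOWN_SPECIES", name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def reaction(self, rid: str) -> Reaction:
        for rx in self.reactions:
            if rx.id == rid:
                return rx
        raise NetworkError("UNKNOWN_REACTION", rid)

    @property
    def x0(self) -> np.ndarray:
        return np.array([sp.x0 for sp in self.species], dtype=float)

    # -- stoichiometry ---------------------------------------------------
    @property
    def S(self) -> np.ndarray:
        """n x r integer stoichiometric matrix (products minus reactants)."""
        if self._S is None:
            S = np.zeros((self.n, self.r), dtype=np.int64)
            for j, rx in enumerate(self.reactions):
                for name, c in rx.reactants:
                    S[self.index(name), j] -= c
                for name, c in rx.products:
                    S[self.index(name), j] += c
            self._S = S
        return self._S

    @property
    def reactant_matrix(self) -> np.ndarray:
        """n x r matrix of reactant coefficients a_ij (kinetic orders)."""
        if self._A is None:
            A = np.zeros((self.n, self.r), dtype=np.int64)
            for j, rx in enumerate(self.reactions):
                for name, c in rx.reactants:
                    A[self.index(name), j] += c
            self._A = A
        return self._A

    @property
    def k(self) -> np.ndarray:
        return np.array([rx.k for rx in self.reactions], dtype=float)

    # -- derived copies --------------------------------------------------
    def with_reactions(self, reactions: Sequence[Reaction]) -> "Network":
        return Network(self.species, reactions, self.declared_conservations)

    def with_species(self, species: Sequence[Species]) -> "Network":
        return Network(species, self.reactions, self.declared_conservations)

    def with_x0(self, x0: np.ndarray) -> "Network":
        sp = tuple(replace(s, x0=float(v)) for s, v in zip(self.species, x0))
        return Network(sp, self.reactions, self.declared_conservations)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Network)
            and self.species == other.species
            and self.reactions == other.reactions
            and self.declared_conservations == other.declared_conservations
        )

    def __repr__(self) -> str:
        return f"<Network n={self.n} species, r={self.r} reactions>"


# ---------------------------------------------------------------------------
# validation


_TAG_PREFIXES = ("deactivation:", "drug:")
_TAG_PLAIN = ("degradation",)


def validate_network(net: Network) -> ValidationReport:
    """Check invariants and collect warnings without raising.

    Errors make the network unusable for simulation (unknown species,
    duplicate ids); warnings flag suspicious but legal structure (species
    in no reaction, zero-initial species only consumed, unknown tags).
    """
    rep = ValidationReport()
    referenced: set[str] = set()
    produced: set[str] = set()
    for rx in net.reactions:
        for name, _ in rx.reactants + rx.products:
            referenced.add(name)
            if name not in net:
                rep.errors.append(
                    ("UNKNOWN_SPECIES", f"reaction {rx.id} references unknown species {name}")
                )
        for name, _ in rx.products:
            produced.add(name)
        for tag in rx.tags:
            if tag not in _TAG_PLAIN and not any(tag.startswith(p) for p in _TAG_PREFIXES):
                rep.warnings.append(("UNKNOWN_TAG", f"reaction {rx.id}: tag {tag!r}"))
    for sp in net.species:
        if sp.name not in referenced:
            rep.warnings.append(("DANGLING_SPECIES", sp.name))
        elif sp.x0 == 0 and sp.name not in produced:
            consumed = any(
                sp.name in (n for n, _ in rx.reactants) for rx in net.reactions
            )
            if consumed:
                rep.warnings.append(
                    ("UNREACHABLE_SPECIES", f"{sp.name}: x0 = 0 and never produced")
                )
    return rep


# ---------------------------------------------------------------------------
# text format


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _parse_side(text: str, line_no: int) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if text == "0":
        return ()
    terms = []
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            terms.append((parts[0], 1))
        elif len(parts) == 2:
            try:
                coeff = int(parts[0])
            except ValueError:
                raise ParseError(f"bad coefficient {parts[0]!r}", line_no) from None
            terms.append((parts[1], coeff))
        else:
            raise ParseError(f"cannot parse term {term.strip()!r}", line_no)
    return tuple(terms)


def loads_network(text: str, check: bool = True) -> Network:
    species: list[Species] = []
    reactions: list[Reaction] = []
    conservations: list[DeclaredConservation] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        kind, _, rest = line.partition(" ")
        if kind == "SPECIES":
            parts = rest.split()
            if len(parts) < 2:
                raise ParseError("SPECIES needs a name and x0", line_no)
            name = parts[0]
            try:
                x0 = float(parts[1])
            except ValueError:
                raise ParseError(f"bad x0 {parts[1]!r}", line_no) from None
            composition = None
            phospho = None
            for extra in parts[2:]:
                if extra.startswith("composition="):
                    composition = tuple(extra[len("composition="):].split("+"))
                elif extra.startswith("phospho="):
                    phospho = extra[len("phospho="):]
                else:
                    raise ParseError(f"unknown SPECIES attribute {extra!r}", line_no)
            try:
                species.append(Species(name, x0, composition, phospho))
            except NetworkError as e:
                raise ParseError(str(e), line_no) from None
        elif kind == "REACTION":
            fields = [f.strip() for f in rest.split(";")]
            head = fields[0]
            rid, _, eq = head.partition(" ")
            if "->" not in eq:
                raise ParseError("REACTION needs '->'", line_no)
            lhs, rhs = eq.split("->", 1)
            k = None
            tags: frozenset[str] = frozenset()
            for f in fields[1:]:
                if f.startswith("k="):
                    try:
                        k = float(f[2:])
                    except ValueError:
                        raise ParseError(f"bad rate {f!r}", line_no) from None
                elif f.startswith("tags="):
                    tags = frozenset(t for t in f[5:].split(",") if t)
                elif f:
                    raise ParseError(f"unknown REACTION field {f!r}", line_no)
            if k is None:
                raise ParseError("REACTION missing k=", line_no)
            try:
                reactions.append(
                    Reaction(
                        rid,
                        _parse_side(lhs, line_no),
                        _parse_side(rhs, line_no),
                        k,
                        tags,
                    )
                )
            except NetworkError as e:
                raise ParseError(str(e), line_no) from None
        elif kind == "CONSERVATION":
            parts = rest.split(None, 1)
            if len(parts) != 2:
                raise ParseError("CONSERVATION needs a name and terms", line_no)
            name, terms_text = parts
            terms = []
            for term in terms_text.split("+"):
                tp = term.split()
                if len(tp) != 2:
                    raise ParseError(f"bad CONSERVATION term {term.strip()!r}", line_no)
                try:
                    coeff = Fraction(tp[0])
                except ValueError:
                    raise ParseError(f"bad coefficient {tp[0]!r}", line_no) from None
                terms.append((coeff, tp[1]))
            conservations.append(DeclaredConservation(name, tuple(terms)))
        else:
            raise ParseError(f"unknown directive {kind!r}", line_no)
    if not species:
        raise ParseError("no SPECIES lines found")
    return Network(species, reactions, conservations, check=check)


def load_network(path: str | Path, check: bool = True) -> Network:
    """Parse a network file in the interchange format."""
    return loads_network(Path(path).read_text(encoding="utf-8"), check=check)


def dumps_network(net: Network) -> str:
    """Canonical serialization; save/load round-trips are the identity."""
    out = io.StringIO()
    for sp in net.species:
        line = f"SPECIES {sp.name} {_fmt_float(sp.x0)}"
        if sp.composition is not None:
            line += " composition=" + "+".join(sp.composition)
        if sp.phospho_state is not None:
            line += f" phospho={sp.phospho_state}"
        out.write(line + "\n")
    for rx in net.reactions:
        line = f"REACTION {rx.id} {rx.equation()} ; k={_fmt_float(rx.k)}"
        if rx.tags:
            line += " ; tags=" + ",".join(sorted(rx.tags))
        out.write(line + "\n")
    for con in net.declared_conservations:
        terms = " + ".join(f"{c} {s}" for c, s in con.terms)
        out.write(f"CONSERVATION {con.name} {terms}\n")
    return out.getvalue()


def save_network(net: Network, path: str | Path) -> None:
    Path(path).write_text(dumps_network(net), encoding="utf-8")


# ---------------------------------------------------------------------------
# tabular export


def species_table(net: Network) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [sp.name for sp in net.species],
            "x0": [sp.x0 for sp in net.species],
            "composition": [
                "+".join(sp.composition) if sp.composition else "" for sp in net.species
            ],
        }
    )


def reaction_table(net: Network) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [rx.id for rx in net.reactions],
            "equation": [rx.equation() for rx in net.reactions],
            "k": [rx.k for rx in net.reactions],
            "tags": [",".join(sorted(rx.tags)) for rx in net.reactions],
        }
    )
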