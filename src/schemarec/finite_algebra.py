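"""Finite monoids and groups as explicit Cayley tables.

A monoid here is the algebraic schema underlying a series of learning tasks:
a finite set of abstract actions with an associative composition and a unit
(the "do nothing" action).  Cyclic groups model rotation schemas, the Klein
four-group models reflection (reciprocal) schemas, and arbitrary
transformation monoids arise by closing a set of observed stimulus
transformations under composition.

Element labels are arbitrary hashable identifiers.  Canonical constructors
use the integers ``0..n-1`` with ``0`` as the unit; user-supplied monoids
keep whatever labels they came with.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

__all__ = [
    "Monoid",
    "Endomap",
    "Violation",
    "CarrierMismatchError",
    "make_cyclic_monoid",
    "make_klein_monoid",
    "validate_monoid",
    "close_under_composition",
    "compose",
    "identity_endomap",
    "monoid_isomorphisms",
    "find_isomorphism",
    "automorphisms",
    "monoid_to_dict",
    "monoid_from_dict",
]


class CarrierMismatchError(ValueError):
    """Raised when endomaps over different carriers are combined."""


@dataclass(frozen=True)
class Violation:
    """A broken monoid/action law together with the witnessing elements."""

    law: str
    witness: tuple

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.law} violated at {self.witness!r}"


@dataclass(frozen=True)
class Monoid:
    """A finite monoid given by its Cayley table.

    ``table[i][j]`` is the label of ``elements[i] * elements[j]`` (row =
    left argument).  Constructors guarantee the monoid laws; arbitrary
    tables can be checked with :func:`validate_monoid`.
    """

    elements: tuple
    unit: object
    table: tuple
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {e: i for i, e in enumerate(self.elements)})

    def index(self, a) -> int:
        try:
            return self._index[a]
        except KeyError:
            raise KeyError(f"unknown monoid element {a!r}") from None

    def mul(self, a, b):
        """The product ``a * b``."""
        return self.table[self.index(a)][self.index(b)]

    def __len__(self) -> int:
        return len(self.elements)

    def is_group(self) -> bool:
        return all(
            any(self.mul(a, b) == self.unit and self.mul(b, a) == self.unit for b in self.elements)
            for a in self.elements
        )


@dataclass(frozen=True)
class Endomap:
    """A total map from a finite carrier to itself.

    ``images[i]`` is the image of ``carrier[i]``; one action component of a
    learning task (the effect of a single cue shape on the stimulus set).
    """

    carrier: tuple
    images: tuple
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.carrier)})
        bad = [x for x in self.images if x not in self._index]
        if bad:
            raise ValueError(f"image {bad[0]!r} not in carrier")
        if len(self.images) != len(self.carrier):
            raise ValueError("endomap must be total on its carrier")

    @classmethod
    def from_mapping(cls, carrier: Sequence, mapping: Mapping) -> "Endomap":
        carrier = tuple(carrier)
        return cls(carrier, tuple(mapping[s] for s in carrier))

    def __call__(self, s):
        return self.images[self._index[s]]

    def is_bijection(self) -> bool:
        return len(set(self.images)) == len(self.carrier)

    def as_dict(self) -> dict:
        return dict(zip(self.carrier, self.images))


def identity_endomap(carrier: Sequence) -> Endomap:
    carrier = tuple(carrier)
    return Endomap(carrier, carrier)


def compose(f: Endomap, g: Endomap) -> Endomap:
    """Function composition ``f after g`` (apply ``g`` first, then ``f``)."""
    if f.carrier != g.carrier:
        raise CarrierMismatchError("endomaps defined over different carriers")
    return Endomap(f.carrier, tuple(f(x) for x in g.images))


def make_cyclic_monoid(n: int) -> Monoid:
    """The cyclic group Z/nZ: integers 0..n-1 under addition modulo n.

    ``n = 3`` is the rotation schema of the triangle tasks; ``n = 1`` is the
    trivial monoid.
    """
    if not isinstance(n, int) or n < 1:
        raise ValueError(f"cyclic monoid order must be a positive integer, got {n!r}")
    elements = tuple(range(n))
    table = tuple(tuple((i + j) % n for j in elements) for i in elements)
    return Monoid(elements, 0, table)


def make_klein_monoid() -> Monoid:
    """The Klein four-group: every non-unit element is a self-inverse.

    Realised as {0,1,2,3} under bitwise xor; 1 and 2 play the role of
    horizontal/vertical reflection, 3 their diagonal composite.
    """
    elements = (0, 1, 2, 3)
    table = tuple(tuple(i ^ j for j in elements) for i in elements)
    return Monoid(elements, 0, table)


def validate_monoid(m: Monoid) -> list[Violation]:
    """Check closure, unitality and associativity; return all violations.

    Violations are returned (not raised) so invalid candidate tables can be
    inspected.
    """
    out: list[Violation] = []
    elems = set(m.elements)
    if m.unit not in elems:
        out.append(Violation("unital", (m.unit,)))
        return out
    for a in m.elements:
        for b in m.elements:
            if m.mul(a, b) not in elems:
                out.append(Violation("closure", (a, b)))
    if any(v.law == "closure" for v in out):
        return out
    for a in m.elements:
        if m.mul(m.unit, a) != a or m.mul(a, m.unit) != a:
            out.append(Violation("unital", (a,)))
    for a, b, c in itertools.product(m.elements, repeat=3):
        if m.mul(a, m.mul(b, c)) != m.mul(m.mul(a, b), c):
            out.append(Violation("associative", (a, b, c)))
    return out


def close_under_composition(
    components: Mapping[object, Endomap],
) -> tuple[Monoid, dict]:
    """Generate the transformation monoid of a set of observed components.

    Partial tasks present only some actions of the schema (e.g. the two
    90-degree rotations of a cyclic-4 task); the remaining actions are
    composites and are recovered here by saturating the generators under
    function composition, with the identity adjoined as unit.

    Returns the monoid (elements ``0..k-1`` in discovery order, ``0`` the
    unit) and the assignment of each element to its distinct endomap.  The
    assignment is a monoid homomorphism into endomaps under the convention
    ``table(a, b) = endomap(a) after endomap(b)``.
    """
    comps = list(components.values())
    if not comps:
        raise ValueError("at least one component is required")
    carrier = comps[0].carrier
    for c in comps[1:]:
        if c.carrier != carrier:
            raise CarrierMismatchError(
                f"components defined over mismatched carriers: {carrier!r} vs {c.carrier!r}"
            )
    discovered: list[Endomap] = [identity_endomap(carrier)]
    seen = {discovered[0].images}
    for c in comps:
        if c.images not in seen:
            discovered.append(c)
            seen.add(c.images)
    # breadth-first product saturation; discovery order fixes element labels
    frontier = list(discovered)
    while frontier:
        new: list[Endomap] = []
        for f in discovered:
            for g in frontier:
                for h in (compose(f, g), compose(g, f)):
                    if h.images not in seen:
                        seen.add(h.images)
                        new.append(h)
        discovered.extend(new)
        frontier = new
    k = len(discovered)
    index = {e.images: i for i, e in enumerate(discovered)}
    table = tuple(
        tuple(index[compose(discovered[i], discovered[j]).images] for j in range(k))
        for i in range(k)
    )
    monoid = Monoid(tuple(range(k)), 0, table)
    assignment = {i: discovered[i] for i in range(k)}
    return monoid, assignment


def monoid_isomorphisms(m1: Monoid, m2: Monoid) -> Iterator[dict]:
    """Brute-force iterator over all isomorphisms ``m1 -> m2``.

    Sizes at play are small (at most 8 in the task fixtures), so exhaustive
    search over bijections is deliberate.
    """
    if len(m1) != len(m2):
        return
    rest1 = [a for a in m1.elements if a != m1.unit]
    rest2 = [a for a in m2.elements if a != m2.unit]
    for perm in itertools.permutations(rest2):
        phi = {m1.unit: m2.unit}
        phi.update(zip(rest1, perm))
        if all(
            phi[m1.mul(a, b)] == m2.mul(phi[a], phi[b])
            for a in m1.elements
            for b in m1.elements
        ):
            yield phi


def find_isomorphism(m1: Monoid, m2: Monoid) -> Optional[dict]:
    """First isomorphism ``m1 -> m2`` in a deterministic order, or None."""
    return next(monoid_isomorphisms(m1, m2), None)


def automorphisms(m: Monoid) -> list[dict]:
    return list(monoid_isomorphisms(m, m))


def monoid_to_dict(m: Monoid) -> dict:
    """JSON form: ``{"elements": [...], "unit": ..., "table": [[...]]}``."""
    return {
        "elements": list(m.elements),
        "unit": m.unit,
        "table": [list(row) for row in m.table],
    }


def monoid_from_dict(obj: Mapping) -> Monoid:
    for key in ("elements", "unit", "table"):
        if key not in obj:
            raise ValueError(f"monoid object missing field {key!r}")
    elements = tuple(obj["elements"])
    table = obj["table"]
    if len(table) != len(elements) or any(len(row) != len(elements) for row in table):
        raise ValueError("monoid table must be square with one row per element")
    return Monoid(elements, obj["unit"], tuple(tuple(row) for row in table))
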