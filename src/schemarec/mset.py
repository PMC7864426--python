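"""Learning tasks as M-set representations and their equivariant maps.

A learning task pairs a stimulus set (the carrier) with an action of a
monoid on it: each monoid element acts as one cue's stimulus-to-stimulus
transformation.  An equivariant map between two tasks is a function on
stimuli that commutes with every action component — the formal notion of an
analogy between tasks.  What a participant observes is only the forgetful
view: carriers and functions, with the algebraic indexing hidden.

Carrier ordering is never semantically meaningful (permuting the rows or
columns of a task table does not change the actions); it is fixed purely so
that enumerations are deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .finite_algebra import Endomap, Monoid, Violation, automorphisms

__all__ = [
    "MSetRep",
    "HomSet",
    "MonoidMismatchError",
    "SizeCapError",
    "regular_representation",
    "trivial_representation",
    "validate_action",
    "component",
    "enumerate_equivariant_maps",
    "is_equivariant",
    "forget",
    "mset_to_dict",
    "mset_from_dict",
]

#: Largest carrier admitted by exhaustive hom-set enumeration by default.
DEFAULT_MAX_CARRIER = 8


class MonoidMismatchError(ValueError):
    """Raised when two representations do not share one literal monoid."""


class SizeCapError(ValueError):
    """Raised when an exhaustive enumeration would exceed the size cap."""


@dataclass(frozen=True)
class MSetRep:
    """A monoid action on a finite stimulus set (one learning task).

    ``action[i][j]`` is the label of ``monoid.elements[i]`` acting on
    ``carrier[j]``.
    """

    monoid: Monoid
    carrier: tuple
    action: tuple
    _cindex: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_cindex", {s: i for i, s in enumerate(self.carrier)})

    @classmethod
    def from_mapping(cls, monoid: Monoid, carrier: Sequence, action: Mapping) -> "MSetRep":
        """Build from ``{element: {stimulus: stimulus}}`` nested mappings."""
        carrier = tuple(carrier)
        rows = tuple(tuple(action[a][s] for s in carrier) for a in monoid.elements)
        return cls(monoid, carrier, rows)

    def act(self, a, s):
        return self.action[self.monoid.index(a)][self._cindex[s]]

    def component(self, a) -> Endomap:
        """The endomap transpose of element ``a``: ``s -> act(a, s)``."""
        return Endomap(self.carrier, self.action[self.monoid.index(a)])

    def is_faithful(self) -> bool:
        """Whether distinct elements act as distinct endomaps."""
        rows = set(self.action)
        return len(rows) == len(self.monoid)


@dataclass(frozen=True)
class HomSet:
    """All equivariant maps between two task carriers, in enumeration order.

    Each map is a ``{source stimulus: target stimulus}`` dict.
    """

    source: MSetRep
    target: MSetRep
    maps: tuple

    def __len__(self) -> int:
        return len(self.maps)

    def __iter__(self):
        return iter(self.maps)


def regular_representation(m: Monoid, carrier_labels: Optional[Sequence] = None) -> MSetRep:
    """The monoid acting on itself by left multiplication.

    ``carrier_labels[i]`` relabels element ``m.elements[i]``; this is the
    faithful task form used in the induction experiments (fresh trigram
    vocabulary, same algebra).
    """
    if carrier_labels is None:
        carrier = m.elements
    else:
        carrier = tuple(carrier_labels)
        if len(carrier) != len(m.elements):
            raise ValueError(
                f"need {len(m.elements)} carrier labels, got {len(carrier)}"
            )
        if len(set(carrier)) != len(carrier):
            raise ValueError("carrier labels must be distinct")
    relabel = dict(zip(m.elements, carrier))
    action = tuple(
        tuple(relabel[m.mul(a, b)] for b in m.elements) for a in m.elements
    )
    return MSetRep(m, carrier, action)


def trivial_representation(m: Monoid, carrier: Sequence) -> MSetRep:
    """Every element acts as the identity (each stimulus is a fixed point)."""
    carrier = tuple(carrier)
    return MSetRep(m, carrier, tuple(carrier for _ in m.elements))


def validate_action(rep: MSetRep) -> list[Violation]:
    """Check the identity and compatibility laws of a monoid action."""
    out: list[Violation] = []
    m = rep.monoid
    for s in rep.carrier:
        if rep.act(m.unit, s) != s:
            out.append(Violation("identity", (s,)))
    for a in m.elements:
        for b in m.elements:
            for s in rep.carrier:
                if rep.act(m.mul(a, b), s) != rep.act(a, rep.act(b, s)):
                    out.append(Violation("compatibility", (a, b, s)))
    return out


def component(rep: MSetRep, a) -> Endomap:
    return rep.component(a)


def forget(rep: MSetRep) -> tuple:
    """The forgetful view: the stimulus set with no action attached."""
    return rep.carrier


def is_equivariant(f: Mapping, x: MSetRep, y: MSetRep) -> bool:
    """Whether ``f`` commutes with every action component (definition form)."""
    return all(
        f[x.act(a, s)] == y.act(a, f[s]) for a in x.monoid.elements for s in x.carrier
    )


def enumerate_equivariant_maps(
    x: MSetRep,
    y: MSetRep,
    up_to_automorphism: bool = False,
    max_carrier: int = DEFAULT_MAX_CARRIER,
) -> HomSet:
    """Exhaustively enumerate the equivariant maps from ``x`` to ``y``.

    All ``|target| ** |source|`` functions are generated and filtered by the
    equivariance law; the order (lexicographic over the target carrier) is
    deterministic.  Maps are not required to be bijections: carriers of
    different sizes give homomorphic, not merely isomorphic, task relations.

    With ``up_to_automorphism=True`` a function is kept if it is equivariant
    under *some* automorphism reindexing of the target's components.  This is
    the candidate-analogy pool available to a learner who has not yet
    resolved which cue of one task corresponds to which cue of the other;
    for two distinct cyclic-3 tasks it has six members, whereas the strict
    hom-set (the one the reconstruction ranges over) has three.
    """
    if x.monoid != y.monoid:
        raise MonoidMismatchError("representations are over different monoids")
    n_src, n_tgt = len(x.carrier), len(y.carrier)
    if n_src > max_carrier or n_tgt > max_carrier:
        raise SizeCapError(
            f"carrier exceeds enumeration cap ({max_carrier}); raise max_carrier"
        )
    m = x.monoid
    elems = range(len(m))
    xact = tuple(tuple(x._cindex[v] for v in row) for row in x.action)
    yact = tuple(tuple(y._cindex[v] for v in row) for row in y.action)
    twists: list[tuple] = [tuple(elems)]
    if up_to_automorphism:
        twists = [
            tuple(m.index(phi[a]) for a in m.elements)
            for phi in automorphisms(m)
        ]
    maps = []
    for images in itertools.product(range(n_tgt), repeat=n_src):
        for phi in twists:
            if all(
                images[xact[a][s]] == yact[phi[a]][images[s]]
                for a in elems
                for s in range(n_src)
            ):
                maps.append(
                    {x.carrier[s]: y.carrier[images[s]] for s in range(n_src)}
                )
                break
    return HomSet(x, y, tuple(maps))


def mset_to_dict(rep: MSetRep, inline_monoid: bool = True) -> dict:
    """JSON form: ``{"monoid": ..., "carrier": [...], "action": {e: {s: s}}}``.

    JSON object keys are strings, so element and stimulus keys are written
    via ``str``; readers resolve them against the declared label lists.
    """
    obj: dict = {
        "carrier": list(rep.carrier),
        "action": {
            str(a): {str(s): rep.act(a, s) for s in rep.carrier}
            for a in rep.monoid.elements
        },
    }
    if inline_monoid:
        from .finite_algebra import monoid_to_dict

        obj["monoid"] = monoid_to_dict(rep.monoid)
    return obj


def mset_from_dict(obj: Mapping, monoid: Optional[Monoid] = None) -> MSetRep:
    if monoid is None:
        from .finite_algebra import monoid_from_dict

        monoid = monoid_from_dict(obj["monoid"])
    carrier = tuple(obj["carrier"])
    by_elem = {str(a): a for a in monoid.elements}
    by_stim = {str(s): s for s in carrier}
    raw = obj["action"]
    action = {}
    for key, row in raw.items():
        if key not in by_elem:
            raise ValueError(f"action row for unknown element {key!r}")
        action[by_elem[key]] = {by_stim[s]: t for s, t in row.items()}
    return MSetRep.from_mapping(monoid, carrier, action)
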