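"""Induction as reconstruction: computing the end of Hom(U-, U-).

Given a finite diagram of learned tasks (M-set representations over one
monoid, with every equivariant map between them), the underlying monoid is
recovered as the end of the bivariate forgetful hom-functor.  Concretely, an
apex element is a tuple of endomaps — one per task — such that every
equivariant map in the diagram commutes with the tuple (dinaturality); the
end collects exactly the distinct consistent tuples (existence and
uniqueness), and composing tuples componentwise equips the apex with the
reconstructed monoid structure.

The search is the incremental generate-and-test procedure a learner could
run: start from the empty wedge (no prior knowledge of the actions),
hypothesise a new apex element with a component tuple, keep it only if every
commutativity test passes, and stop when no consistent tuple is missing and
none is duplicated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .finite_algebra import Endomap, Monoid, compose, find_isomorphism, identity_endomap
from .mset import (
    DEFAULT_MAX_CARRIER,
    HomSet,
    MSetRep,
    MonoidMismatchError,
    SizeCapError,
    enumerate_equivariant_maps,
    validate_action,
)

__all__ = [
    "TaskDiagram",
    "Wedge",
    "EndResult",
    "build_task_diagram",
    "is_dinatural",
    "nat_oracle",
    "compute_end",
    "universality_failures",
    "check_reconstruction",
]

logger = logging.getLogger(__name__)

#: Cap on the number of candidate tuples brute-forced by the oracle.
DEFAULT_MAX_TUPLES = 10_000_000


@dataclass(frozen=True)
class TaskDiagram:
    """A finite diagram in the category of M-sets.

    ``objects`` are the learned tasks; ``homs[(i, j)]`` is the full hom-set
    of equivariant maps from object ``i`` to object ``j`` (self-pairs
    included — they contain the within-task action components' centralizer).
    """

    monoid: Monoid
    objects: tuple
    homs: dict

    def hom(self, i: int, j: int) -> HomSet:
        return self.homs[(i, j)]


@dataclass(frozen=True)
class Wedge:
    """An apex set with one endomap per task for each apex element.

    ``components[d]`` is the tuple of endomaps selected by apex element
    ``d``, aligned with the diagram's object order.
    """

    apex: tuple
    components: dict

    def component(self, d, i: int) -> Endomap:
        return self.components[d][i]


@dataclass(frozen=True)
class EndResult:
    """The universal wedge over a task diagram.

    ``tuples[k]`` is the endomap tuple of apex element ``k`` (apex labels
    are 0, 1, 2, ... in discovery order; their identity matters only up to
    distinguishability).  ``induced_monoid`` is the composition structure on
    the apex.  ``faithful`` records whether some object was a faithful
    representation: only then is the induced monoid guaranteed to be the
    generating monoid rather than a diagram-relative end.
    """

    wedge: Wedge
    tuples: tuple
    induced_monoid: Monoid
    faithful: bool
    log: tuple
    diagram: TaskDiagram

    @property
    def apex_size(self) -> int:
        return len(self.wedge.apex)


def build_task_diagram(
    tasks: Sequence[MSetRep], max_carrier: int = DEFAULT_MAX_CARRIER
) -> TaskDiagram:
    """Enumerate every equivariant map between every ordered pair of tasks."""
    tasks = tuple(tasks)
    if not tasks:
        raise ValueError("a task diagram needs at least one task")
    monoid = tasks[0].monoid
    for t in tasks[1:]:
        if t.monoid != monoid:
            raise MonoidMismatchError("all tasks in a diagram must share one monoid")
    for k, t in enumerate(tasks):
        violations = validate_action(t)
        if violations:
            raise ValueError(f"task {k} is not a lawful M-set: {violations[0]}")
    homs = {
        (i, j): enumerate_equivariant_maps(tasks[i], tasks[j], max_carrier=max_carrier)
        for i in range(len(tasks))
        for j in range(len(tasks))
    }
    return TaskDiagram(monoid, tasks, homs)


def is_dinatural(w: Wedge, d: TaskDiagram) -> tuple[bool, list]:
    """Test the wedge square for every equivariant map and apex element.

    Returns ``(ok, witnesses)``; each witness is ``(i, j, f, apex_element,
    stimulus)`` at which ``f . w_i != w_j . f``.  The empty wedge is
    trivially dinatural.
    """
    witnesses = []
    for (i, j), hom in d.homs.items():
        for f in hom:
            for elem in w.apex:
                ti, tj = w.component(elem, i), w.component(elem, j)
                for s in d.objects[i].carrier:
                    if f[ti(s)] != tj(f[s]):
                        witnesses.append((i, j, f, elem, s))
                        break
    return (not witnesses, witnesses)


def _all_endomaps(carrier: tuple):
    for images in itertools.product(carrier, repeat=len(carrier)):
        yield Endomap(carrier, images)


def nat_oracle(d: TaskDiagram, max_tuples: int = DEFAULT_MAX_TUPLES) -> list:
    """Brute-force the natural transformations of the forgetful view.

    Enumerates *all* tuples of endomaps — one per object, drawn from the
    full function space, not only the action components — and keeps those
    with which every equivariant map in the diagram commutes.  Serves as the
    independent oracle for :func:`compute_end`.
    """
    sizes = [len(x.carrier) ** len(x.carrier) for x in d.objects]
    total = 1
    for s in sizes:
        total *= s
    if total > max_tuples:
        raise SizeCapError(f"{total} candidate tuples exceed cap {max_tuples}")
    candidates = [list(_all_endomaps(x.carrier)) for x in d.objects]
    out = []
    n = len(d.objects)
    for tup in itertools.product(*candidates):
        ok = True
        for (i, j), hom in d.homs.items():
            ci = d.objects[i].carrier
            for f in hom:
                if not all(f[tup[i](s)] == tup[j](f[s]) for s in ci):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(tup)
    return out


def compute_end(
    d: TaskDiagram,
    single_map: bool = False,
    max_tuples: int = DEFAULT_MAX_TUPLES,
) -> EndResult:
    """Directed search for the universal wedge.

    Candidate components for each object are pruned first by that object's
    equivariant self-maps (the cheapest constraint), then joined across
    objects under the cross-task maps.  Every accepted hypothesis strictly
    enlarges the apex by one new consistent tuple, so the search walks the
    inclusion preorder of wedges monotonically from the empty wedge to the
    terminal one.

    ``single_map=True`` tests dinaturality against only the first enumerated
    equivariant map per ordered pair instead of all of them, mirroring a
    learner who fixes one analogy f0 per task pair.  (For diagrams of
    faithful group tasks a single bijective analogy already cuts the tuple
    space to the monoid, so both variants agree there.)
    """
    n = len(d.objects)
    log: list = []

    def homs_used(i: int, j: int):
        maps = d.hom(i, j).maps
        if single_map and i != j and maps:
            return maps[:1]
        return maps

    # per-object candidates: endomaps commuting with every self-map
    candidates: list[list[Endomap]] = []
    for i, x in enumerate(d.objects):
        size = len(x.carrier) ** len(x.carrier)
        if size > max_tuples:
            raise SizeCapError(f"object {i} has {size} endomaps, exceeds cap")
        kept = []
        for t in _all_endomaps(x.carrier):
            bad = None
            for f in homs_used(i, i):
                if not all(f[t(s)] == t(f[s]) for s in x.carrier):
                    bad = f
                    break
            if bad is None:
                kept.append(t)
            else:
                logger.debug("reject component %r on object %d (self-map %r)", t.images, i, bad)
        candidates.append(kept)
        log.append(("pruned", i, len(kept)))

    accepted: list[tuple] = []

    def extend(prefix: tuple):
        i = len(prefix)
        if i == n:
            accepted.append(prefix)
            log.append(("accepted", len(accepted) - 1, tuple(t.images for t in prefix)))
            logger.debug("accept apex element %d", len(accepted) - 1)
            return
        for t in candidates[i]:
            ok = True
            witness = None
            for j in range(i):
                cj = d.objects[j].carrier
                ci = d.objects[i].carrier
                for f in homs_used(j, i):
                    if not all(f[prefix[j](s)] == t(f[s]) for s in cj):
                        ok, witness = False, (j, i)
                        break
                if not ok:
                    break
                for f in homs_used(i, j):
                    if not all(f[t(s)] == prefix[j](f[s]) for s in ci):
                        ok, witness = False, (i, j)
                        break
                if not ok:
                    break
            if ok:
                extend(prefix + (t,))
            else:
                log.append(("rejected", tuple(t.images for t in prefix) + (t.images,), witness))
                logger.debug("reject hypothesis at object %d (pair %r)", i, witness)

    extend(())

    apex = tuple(range(len(accepted)))
    wedge = Wedge(apex, {k: accepted[k] for k in apex})
    tuples = tuple(accepted)

    index = {tuple(t.images for t in tup): k for k, tup in enumerate(tuples)}
    unit_tuple = tuple(identity_endomap(x.carrier) for x in d.objects)
    unit_key = tuple(t.images for t in unit_tuple)
    if unit_key not in index:
        raise RuntimeError("end lacks the identity tuple; diagram objects are not lawful M-sets")
    # diagrammatic order (apply d1 first, then d2) makes the apex isomorphic
    # to M itself, not M-op, when the diagram contains a faithful task
    rows = []
    for k1 in apex:
        row = []
        for k2 in apex:
            key = tuple(
                compose(tuples[k2][i], tuples[k1][i]).images for i in range(n)
            )
            if key not in index:
                raise RuntimeError("consistent tuples are not closed under composition")
            row.append(index[key])
        rows.append(tuple(row))
    induced = Monoid(apex, index[unit_key], tuple(rows))
    faithful = any(x.is_faithful() for x in d.objects)
    return EndResult(wedge, tuples, induced, faithful, tuple(log), d)


def universality_failures(w: Wedge, d: TaskDiagram) -> list[str]:
    """Why a dinatural wedge fails to be the end, if it does.

    Existence fails when some consistent tuple is not selected by any apex
    element; uniqueness fails when two apex elements select the same tuple.
    """
    ok, witnesses = is_dinatural(w, d)
    if not ok:
        return [f"dinaturality: {len(witnesses)} commutativity failures"]
    failures = []
    have = {}
    for elem in w.apex:
        key = tuple(t.images for t in w.components[elem])
        if key in have:
            failures.append(f"uniqueness: apex elements {have[key]!r} and {elem!r} are redundant")
        else:
            have[key] = elem
    all_tuples = {tuple(t.images for t in tup) for tup in nat_oracle(d)}
    for key in sorted(all_tuples - set(have)):
        failures.append(f"existence: consistent tuple {key!r} is not selected")
    return failures


def check_reconstruction(
    e: EndResult, ground_truth: Monoid
) -> tuple[bool, Optional[dict] | str]:
    """Is the induced monoid isomorphic to the generating monoid?

    When the diagram contains an order-preserving regular representation the
    canonical witness bijection (apex element to the monoid element its
    tuple right-multiplies by) is returned; otherwise the first isomorphism
    found by brute force.  On failure, a reason string is returned instead.
    """
    induced = e.induced_monoid
    if not e.faithful:
        reason = (
            "diagram-relative end: no object is a faithful representation, "
            "so the apex may strictly exceed the generating monoid"
        )
        if find_isomorphism(induced, ground_truth) is None:
            return False, reason
    if len(induced) != len(ground_truth):
        return False, (
            f"apex has {len(induced)} elements but the ground truth has {len(ground_truth)}"
        )
    for i, obj in enumerate(e.diagram.objects):
        if len(obj.carrier) != len(ground_truth.elements):
            continue
        relabel = dict(zip(ground_truth.elements, obj.carrier))
        if obj.monoid == ground_truth and all(
            obj.act(a, relabel[b]) == relabel[ground_truth.mul(a, b)]
            for a in ground_truth.elements
            for b in ground_truth.elements
        ):
            unit_label = relabel[ground_truth.unit]
            inv = {v: k for k, v in relabel.items()}
            witness = {
                k: inv[e.tuples[k][i](unit_label)] for k in e.wedge.apex
            }
            if all(
                witness[induced.mul(d1, d2)]
                == ground_truth.mul(witness[d1], witness[d2])
                for d1 in induced.elements
                for d2 in induced.elements
            ) and len(set(witness.values())) == len(witness):
                return True, witness
    phi = find_isomorphism(induced, ground_truth)
    if phi is None:
        return False, "induced monoid is not isomorphic to the ground truth"
    return True, phi
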